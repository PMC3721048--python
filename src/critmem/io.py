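"""Plain-text import/export of ensembles, patterns, fits and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .criticality import AvalancheEnsemble, PowerLawFit
from .memory import PatternSet, RetrievalReport


def save_sizes(ensemble: AvalancheEnsemble, path: str | Path, *,
               seed: int | None = None, A_ava: int | None = None) -> None:
    """One avalanche size per line, plus a JSON sidecar with the metadata."""
    path = Path(path)
    np.savetxt(path, ensemble.sizes, fmt="%d")
    sidecar = {
        "N": int(ensemble.N),
        "A_0": int(ensemble.n_discarded),
        "A_ava": int(A_ava if A_ava is not None else ensemble.n_recorded),
        "seed": seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_sizes(path: str | Path, N: int | None = None) -> AvalancheEnsemble:
    """Read a single-column sizes file; N comes from the sidecar if present."""
    path = Path(path)
    sizes = np.loadtxt(path, dtype=np.int64, ndmin=1)
    n_discarded = 0
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        N = N if N is not None else meta.get("N")
        n_discarded = meta.get("A_0", 0)
    if N is None:
        raise ValueError("network size N is required (no sidecar found)")
    return AvalancheEnsemble(sizes=sizes, N=int(N), n_discarded=n_discarded)


def save_fit(fit: PowerLawFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2))


def save_report(report: RetrievalReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def save_patterns(patterns: PatternSet, path: str | Path) -> None:
    """One pattern per line as a string of '0'/'1' characters."""
    lines = ["".join("1" if x else "0" for x in row) for row in patterns.patterns]
    Path(path).write_text("\n".join(lines) + "\n")


def load_patterns(path: str | Path, sparseness: float | None = None) -> PatternSet:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    patterns = np.array([[int(c) for c in ln.strip()] for ln in lines], dtype=np.uint8)
    M, N = patterns.shape
    if sparseness is None:
        sparseness = float(patterns.sum()) / (M * N)
    return PatternSet(patterns=patterns, sparseness=sparseness, M=M, N=N)


def save_checkpoint(path: str | Path, **arrays) -> None:
    """Checkpoint named arrays/scalars (network state, couplings, resources)
    to a compressed npz container."""
    np.savez_compressed(Path(path), **arrays)


def load_checkpoint(path: str | Path) -> dict:
    with np.load(Path(path)) as data:
        return {k: data[k] for k in data.files}
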