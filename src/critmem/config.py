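"""Run configuration.

All defaults reproduce the reference parameter set of the study conditions:
a network of N = 300 non-leaky integrate-and-fire neurons with threshold
θ = 1, sparse binary patterns with 10% active units, and the episode /
plasticity constants listed below.  The external input strength depends on
which criticalization mechanism is active (homeostatic regulation vs.
dynamical synapses), so ``I_ext`` defaults to ``None`` and is resolved per
mode by :meth:`RunConfig.resolved_I_ext`.

Scale convention
----------------
Couplings are stored on the membrane-equation scale: a spike of neuron ``j``
delivers ``J_ij / N`` to neuron ``i``.  Constants that are naturally quoted
on the per-spike *transfer* scale (the memory matrix normalization
``sum_ij W_ij = N`` and the maximal-resource initialization
``T^max = t_max_factor / (u N)``) are converted by a factor ``N`` when they
are installed as couplings; see :func:`critmem.orchestrate.coupling_from_memory`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

MODES = ("pure_memory", "homeostatic", "dynamical")
HOMEOSTATIC_SCOPES = ("global", "trigger_outgoing")

#: Default external input per mechanism (units of θ).
I_EXT_DEFAULTS = {"homeostatic": 0.0067, "pure_memory": 0.0067, "dynamical": 0.025}


@dataclass
class RunConfig:
    """Parameters of a simulation run.

    The defaults are the reference values used throughout: they are *not*
    desk-scale (recording a million avalanches per batch); use
    :meth:`RunConfig.desk` for a scaled-down preset suitable for quick runs.
    """

    N: int = 300                    # network size
    theta: float = 1.0              # firing threshold θ
    sparseness: float = 0.1         # fraction p of active units per pattern
    A_0: int = 10_000               # transient avalanches discarded per episode
    A_ava: int = 1_000_000          # avalanches recorded per batch
    eps_hebb: float = 0.01          # Hebbian relaxation rate ε_hebb
    delta_gamma_max: float = 0.005  # criticality threshold Δγ^max
    Delta_hebb: float = 0.035       # required overlap improvement in Hebbian phase
    Delta_conv: float = 0.03        # required overlap improvement at convergence check
    n_p: int = 1000                 # perturbations per pattern in the rigorous check
    T_L: int = 1000                 # avalanches per homeostatic learning episode
    eps_hom: float = 0.001          # homeostatic rate ε_hom
    I_ext: float | None = None      # external input; None -> mode default
    nu: float = 10.0                # recovery time scale factor, τ_J = τ ν N
    u: float = 0.2                  # fraction of synaptic resources used per spike
    tau: float = 1.0                # external drive time unit (arbitrary)
    alpha: float = 0.02             # memory load α = M / N
    mode: str = "homeostatic"
    seed: int = 0
    max_hebbian_steps: int = 200_000
    max_rounds: int = 50
    homeostatic_scope: str = "global"
    t_max_factor: float = 1.4       # branching-ratio ceiling of uniform T^max init
    trials: int = 10                # trials averaged per load value

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.homeostatic_scope not in HOMEOSTATIC_SCOPES:
            raise ValueError(
                f"homeostatic_scope must be one of {HOMEOSTATIC_SCOPES}, "
                f"got {self.homeostatic_scope!r}"
            )
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not 0 < self.sparseness < 1:
            raise ValueError("sparseness must be in (0, 1)")
        if not 0 < self.u < 1:
            raise ValueError("u must be in (0, 1)")
        if self.I_ext is not None and self.I_ext <= 0:
            raise ValueError("I_ext must be positive")

    # ------------------------------------------------------------------ #

    @property
    def tau_J(self) -> float:
        """Synaptic recovery time constant τ_J = τ ν N."""
        return self.tau * self.nu * self.N

    @property
    def M(self) -> int:
        """Number of stored patterns implied by the load parameter."""
        return int(round(self.alpha * self.N))

    @property
    def n_active(self) -> int:
        """Active units per pattern, round(p N)."""
        return int(round(self.sparseness * self.N))

    def resolved_I_ext(self) -> float:
        if self.I_ext is not None:
            return self.I_ext
        return I_EXT_DEFAULTS[self.mode]

    # ------------------------------------------------------------------ #

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        """Scaled-down preset for desk-scale runs.

        Records 3x10^5 avalanches per batch (enough that the sampling-noise
        floor of Δγ stays well below Δγ^max), discards 10^3 transients,
        uses 100 perturbations per pattern in the rigorous retrieval check
        and 3 trials per load value.
        """
        desk = dict(A_ava=300_000, A_0=1_000, n_p=100, trials=3)
        desk.update(overrides)
        return cls(**desk)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)
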