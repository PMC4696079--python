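"""The four competing demographic scenarios and their parameter priors.

Three regions — MEX and PER at the latitudinal periphery, SAL in the
tropical centre — are related by one of four histories:

* ``TOEMS`` (tropical origin, early Mexican split): MEX splits from the
  tropical (SAL) lineage at the older time t1, PER splits from SAL at
  the more recent time t0.  Vicariance; no founder bottlenecks.
* ``TOEPS`` (tropical origin, early Peruvian split): the mirror image —
  PER splits at t1, MEX at t0.
* ``NOSS`` (northern origin stepping stone): the species originates in
  MEX, colonises SAL at t1 and PER (from SAL) at t0, each founding
  passing through a bottleneck.
* ``SOSS`` (southern origin stepping stone): the mirror from PER.

Pastward, a split is a merge of the derived deme into its source; the
source lineage is resized to Anc x (its modern N_e) at the split, and
founder bottlenecks occupy the oldest ``bottleneck_duration``
generations of the founded deme's existence.

Priors: split times uniform (defaults from isolation-with-migration
posterior ranges: t1 in [150, 300] ka, t0 in [50, 150] ka, rejected
until t0 < t1); Anc multipliers uniform on [1, 20]; bottleneck sizes
exponential with mean 0.2 x the founded deme's modern N_e.  Modern
sizes default to MEX 1.5e6, SAL 2e6, PER 7.5e5 mitochondrial
individuals.  With the one-year generation time, years equal
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .coalsim import DemeConfig, Merge, Resize, ScenarioConfigError

__all__ = [
    "MODELS",
    "REGIONS",
    "ScenarioParams",
    "PriorSet",
    "default_priors",
    "default_demes",
    "build_scenario",
    "draw_parameters",
]

MODELS = ("TOEMS", "TOEPS", "NOSS", "SOSS")
REGIONS = ("MEX", "SAL", "PER")

DEFAULT_NE = {"MEX": 1.5e6, "SAL": 2.0e6, "PER": 7.5e5}


@dataclass(frozen=True)
class ScenarioParams:
    """One draw of the demographic parameters for a scenario.

    Times are in generations (= years) before present; ``anc0``/``anc1``
    multiply the relevant modern N_e; ``bot0``/``bot1`` are bottleneck
    sizes as fractions of the founded deme's modern N_e (stepping-stone
    models only).
    """

    model_id: str
    t0: float
    t1: float
    anc0: float
    anc1: float
    bot0: float | None = None
    bot1: float | None = None

    def __post_init__(self):
        if self.model_id not in MODELS:
            raise ScenarioConfigError(f"unknown model {self.model_id!r}")
        if not (0 < self.t0 < self.t1):
            raise ScenarioConfigError("need 0 < t0 < t1")
        if self.anc0 <= 0 or self.anc1 <= 0:
            raise ScenarioConfigError("ancestral multipliers must be positive")
        if self.model_id in ("NOSS", "SOSS"):
            if self.bot0 is None or self.bot1 is None:
                raise ScenarioConfigError(
                    f"{self.model_id} requires bot0 and bot1"
                )
            if self.bot0 <= 0 or self.bot1 <= 0:
                raise ScenarioConfigError("bottleneck fractions must be positive")


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def draw(self, rng) -> float:
        return float(rng.uniform(self.lo, self.hi))


@dataclass(frozen=True)
class Exponential:
    mean: float

    def draw(self, rng) -> float:
        return float(rng.exponential(self.mean))


@dataclass(frozen=True)
class PriorSet:
    """Prior distributions for the scenario parameters."""

    t0: Uniform = Uniform(50e3, 150e3)
    t1: Uniform = Uniform(150e3, 300e3)
    anc0: Uniform = Uniform(1.0, 20.0)
    anc1: Uniform = Uniform(1.0, 20.0)
    bot_frac0: Exponential = Exponential(0.20)
    bot_frac1: Exponential = Exponential(0.20)
    modern_ne: dict = field(default_factory=lambda: dict(DEFAULT_NE))


def default_priors() -> PriorSet:
    return PriorSet()


def default_demes(
    sample_sizes: dict[str, int], ne: dict[str, float] | None = None
) -> list[DemeConfig]:
    ne = dict(DEFAULT_NE if ne is None else ne)
    return [DemeConfig(r, ne[r], sample_sizes.get(r, 0)) for r in REGIONS]


def _source_chain(model_id: str) -> tuple[str, str, str]:
    """(deme splitting at t0, deme splitting at t1, root deme)."""
    if model_id == "TOEMS":
        return "PER", "MEX", "SAL"
    if model_id == "TOEPS":
        return "MEX", "PER", "SAL"
    if model_id == "NOSS":
        return "PER", "SAL", "MEX"
    if model_id == "SOSS":
        return "MEX", "SAL", "PER"
    raise ScenarioConfigError(f"unknown model {model_id!r}")


def _decline_ladder(
    deme: str, t_start: float, t_end: float,
    size_start: float, size_end: float, n_steps: int,
) -> list:
    """Pastward piecewise-constant approximation of an exponential size
    decline from ``size_start`` (at ``t_start``) to ``size_end`` (at
    ``t_end``); geometric midpoints per step."""
    out = []
    for s in range(n_steps):
        t = t_start + (t_end - t_start) * s / n_steps
        frac = (s + 0.5) / n_steps
        out.append(Resize(t, deme, size_start * (size_end / size_start) ** frac))
    return out


def build_scenario(
    model_id: str,
    params: ScenarioParams,
    demes: list[DemeConfig] | None = None,
    founder_steps: int = 8,
) -> list:
    """Translate scenario parameters into coalescent-simulator events.

    Vicariance models (TOEMS/TOEPS): the peripheral demes merge into
    SAL at their split times and SAL is resized to anc x N_e(SAL)
    pastward of each split.  Stepping-stone models (NOSS/SOSS): the
    colonisation chain is unwound pastward; a founded deme recovers
    from its founder bottleneck by exponential growth, i.e. pastward
    its size declines from the modern value to bot x modern N_e at the
    founding split (approximated by a ``founder_steps``-step ladder —
    a fixed-duration bottleneck pulse at these effective sizes would be
    genealogically invisible).  Ancestral Anc resizes apply to the
    source lineage at each split.
    """
    if params.model_id != model_id:
        raise ScenarioConfigError(
            f"params built for {params.model_id}, not {model_id}"
        )
    if demes is None:
        demes = default_demes({})
    ne = {d.label: d.N_e for d in demes}
    events: list = []
    if model_id in ("TOEMS", "TOEPS"):
        first, early, root = _source_chain(model_id)
        # t0: recent split (deme `first` re-joins SAL)
        events.append(Merge(params.t0, first, root))
        events.append(Resize(params.t0, root, params.anc0 * ne[root]))
        events.append(Merge(params.t1, early, root))
        events.append(Resize(params.t1, root, params.anc1 * ne[root]))
    else:
        tip, mid, root = _source_chain(model_id)
        # t0: `tip` was founded from `mid`; t1: `mid` founded from `root`
        events.extend(
            _decline_ladder(
                tip, 0.0, params.t0, ne[tip], params.bot0 * ne[tip],
                founder_steps,
            )
        )
        events.append(Merge(params.t0, tip, mid))
        events.append(Resize(params.t0, mid, params.anc0 * ne[mid]))
        events.extend(
            _decline_ladder(
                mid, params.t0, params.t1,
                params.anc0 * ne[mid], params.bot1 * ne[mid], founder_steps,
            )
        )
        events.append(Merge(params.t1, mid, root))
        events.append(Resize(params.t1, root, params.anc1 * ne[root]))
    return sorted(events, key=lambda e: e.time)


def draw_parameters(
    priors: PriorSet, model_id: str, rng_seed, max_tries: int = 1000
) -> ScenarioParams:
    """Draw one parameter vector; t0 < t1 enforced by rejection."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for _ in range(max_tries):
        t0 = priors.t0.draw(rng)
        t1 = priors.t1.draw(rng)
        if t0 >= t1:
            continue
        anc0 = priors.anc0.draw(rng)
        anc1 = priors.anc1.draw(rng)
        if model_id in ("NOSS", "SOSS"):
            # bottleneck must be a positive fraction; redraw zero-adjacent values
            bot0 = max(priors.bot_frac0.draw(rng), 1e-6)
            bot1 = max(priors.bot_frac1.draw(rng), 1e-6)
        else:
            bot0 = bot1 = None
        return ScenarioParams(model_id, t0, t1, anc0, anc1, bot0, bot1)
    raise ScenarioConfigError(
        "rejection rate too high: time priors are incompatible (t0 >= t1)"
    )
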