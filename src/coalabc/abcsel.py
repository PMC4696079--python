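"""ABC model choice and parameter estimation over simulated reference tables.

The summary-statistic vector has a fixed, versioned order of 15 entries:
for each region (MEX, SAL, PER) the nucleotide diversity pi, haplotype
diversity H, segregating sites S and Tajima's D, followed by pairwise
Phi_ST for MEX-SAL, MEX-PER and SAL-PER (Phi_ST on raw difference
counts; a haplotype-frequency F_ST is available as a config switch).
D is undefined when S = 0 and is imputed as 0 (flagged per row).

Model selection follows the rejection / regression-adjustment ABC
recipe: statistics are standardised by their median absolute deviation,
the delta-fraction of simulations nearest the observed vector (Euclid)
is retained, and posterior model probabilities are either the accepted
model frequencies (rejection) or the class probabilities of a
single-hidden-layer neural network classifier fit to the accepted rows
and evaluated at the observed vector.  Parameter estimation adjusts the
accepted parameter values (log scale) with a neural-network regression
toward the observed statistics and reports Epanechnikov-weighted
median, mean and mode.  Cross-validation treats held-out table rows as
pseudo-observed datasets (leave-one-out) and reports confusion matrices
and percent correctly assigned per tolerance level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalsim, scenarios, sumstats
from .alignment import Alignment
from .scenarios import MODELS, REGIONS

__all__ = [
    "STAT_NAMES",
    "PARAM_NAMES",
    "AbcSettings",
    "ReferenceTable",
    "ModelSelectionResult",
    "ParamPosterior",
    "CrossValidationResult",
    "compute_sumstats",
    "sumstats_from_matrix",
    "simulate_reference_table",
    "model_select",
    "estimate_parameters",
    "cross_validate",
]

# Versioned statistic order (v1).
STAT_NAMES = tuple(
    f"{r}_{s}" for r in REGIONS for s in ("pi", "H", "S", "D")
) + ("phi_MEX_SAL", "phi_MEX_PER", "phi_SAL_PER")

PARAM_NAMES = ("t0", "t1", "anc0", "anc1", "bot0", "bot1")

_PAIRS = ((0, 1), (0, 2), (1, 2))


def _counts4(sub: np.ndarray) -> np.ndarray:
    """4 x S allele counts per variant column."""
    return np.stack([(sub == a).sum(axis=0) for a in range(4)])


_HASH_RNG = np.random.default_rng(0x5EED)
_HASH_WEIGHTS = _HASH_RNG.integers(1, 2**64 - 1, size=4096, dtype=np.uint64)


def _row_hashes(sub: np.ndarray) -> np.ndarray:
    """64-bit row fingerprints (multiply-shift; collisions ~ n^2/2^64)."""
    S = sub.shape[1]
    w = _HASH_WEIGHTS
    if S > w.size:
        w = np.concatenate([w] * (S // w.size + 1))
    with np.errstate(over="ignore"):
        return ((sub.astype(np.uint64) + 2) * w[:S]).sum(axis=1, dtype=np.uint64)


def _hap_counts_rows(sub: np.ndarray) -> np.ndarray:
    if sub.shape[1] == 0:
        return np.array([sub.shape[0]])
    _, c = np.unique(_row_hashes(sub), return_counts=True)
    return c


def _fst_haplotype(sub1, sub2) -> float:
    """Weir-Cockerham-style haplotype-frequency F_ST (config alternative)."""
    m = np.vstack([sub1, sub2])
    v = np.ascontiguousarray(m).view([("", m.dtype)] * m.shape[1]) if m.shape[1] else None
    if v is None:
        return 0.0
    haps, inv = np.unique(v, return_inverse=True)
    n1 = sub1.shape[0]
    h1 = np.bincount(inv[:n1], minlength=haps.size) / n1
    h2 = np.bincount(inv[n1:], minlength=haps.size) / (m.shape[0] - n1)
    hbar = (h1 + h2) / 2.0
    hs = 1.0 - ((h1**2).sum() + (h2**2).sum()) / 2.0
    ht = 1.0 - (hbar**2).sum()
    return float((ht - hs) / ht) if ht > 0 else 0.0


def sumstats_from_matrix(
    var: np.ndarray,
    region_indices: list[np.ndarray],
    L: int,
    fst_kind: str = "phi",
) -> np.ndarray:
    """The 15-entry summary vector from a variant matrix.

    ``var`` holds only variant columns (invariant sites implied); ``L``
    is the full locus length used to turn k into pi.
    """
    out = np.empty(len(STAT_NAMES))
    counts = []
    for ri, idx in enumerate(region_indices):
        sub = var[idx]
        n = idx.size
        c = _counts4(sub)
        # within-region variant columns
        seg = ((c > 0).sum(axis=0) > 1)
        S = int(seg.sum())
        pairs = n * (n - 1) / 2.0
        # columns invariant within the region contribute zero differences
        same = ((c.astype(np.int64) * (c.astype(np.int64) - 1)) // 2).sum()
        k = float(pairs * var.shape[1] - same) / pairs if pairs else 0.0
        hc = _hap_counts_rows(sub)
        p = hc / n
        H = n / (n - 1) * (1.0 - float((p**2).sum())) if n > 1 else 0.0
        D = sumstats.tajimas_d(n, S, k)
        out[4 * ri + 0] = k / L
        out[4 * ri + 1] = H
        out[4 * ri + 2] = S
        out[4 * ri + 3] = 0.0 if math.isnan(D) else D
        counts.append((c, n, sub))
    for pi_, (i, j) in enumerate(_PAIRS):
        ci, ni, si = counts[i]
        cj, nj, sj = counts[j]
        if fst_kind == "phi":
            # delta^2 = difference counts; n^2-based sums overcount the
            # diagonal equally in SS_T and SS_W, so use exact pair sums
            out[12 + pi_] = _phi_pair_exact(ci, cj, ni, nj, var.shape[1])
        else:
            out[12 + pi_] = _fst_haplotype(si, sj)
    return out


def _spd(c: np.ndarray, n: int, ncols: int) -> float:
    """Exact sum over unordered pairs of per-pair difference counts."""
    c64 = c.astype(np.int64)
    same = ((c64 * (c64 - 1)) // 2).sum()
    pairs = n * (n - 1) // 2
    return float(pairs * ncols - same)


def _phi_pair_exact(c1, c2, n1, n2, ncols) -> float:
    N = n1 + n2
    spd1 = _spd(c1, n1, ncols)
    spd2 = _spd(c2, n2, ncols)
    spdU = _spd(c1 + c2, N, ncols)
    ss_w = spd1 / n1 + spd2 / n2
    ss_t = spdU / N
    df_w = N - 2
    if df_w <= 0:
        return 0.0
    sigma_c = ss_w / df_w
    n_coef = N - (n1 * n1 + n2 * n2) / N
    sigma_b = (ss_t - ss_w - sigma_c) / n_coef
    tot = sigma_b + sigma_c
    return float(sigma_b / tot) if tot != 0 else 0.0


def compute_sumstats(
    a: Alignment, fst_kind: str = "phi", deletion: str = "complete"
) -> np.ndarray:
    """Summary vector for an alignment pooled to exactly three regions."""
    demes = a.demes
    if len(demes) != 3:
        raise ValueError(f"expected exactly 3 regions, got {demes}")
    if set(demes) == set(REGIONS):
        order = list(REGIONS)
    else:
        order = sorted(demes)
    keep = a.analysed_sites(deletion)
    m = a.matrix()[:, keep]
    labels = np.array(a.deme_labels)
    idx = [np.where(labels == r)[0] for r in order]
    for r, ix in zip(order, idx):
        if ix.size < 4:
            raise ValueError(f"region {r!r} needs >= 4 sequences")
    # reduce to variant columns; L stays the full analysed length
    seg = (m != m[0]).any(axis=0)
    return sumstats_from_matrix(m[:, seg], idx, int(keep.sum()), fst_kind)


# ---------------------------------------------------------------------------
# reference tables

@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summary statistics) rows."""

    model_id: str
    params: pd.DataFrame  # columns PARAM_NAMES
    stats: np.ndarray  # n_sims x len(STAT_NAMES)
    seed: int | None = None
    stat_names: tuple = STAT_NAMES
    priors_desc: str = ""

    @property
    def n_sims(self) -> int:
        return self.stats.shape[0]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# coalabc reference table v1\n")
            fh.write(f"# model={self.model_id} seed={self.seed}\n")
            if self.priors_desc:
                fh.write(f"# priors: {self.priors_desc}\n")
            fh.write(f"# stats={','.join(self.stat_names)}\n")
            df = pd.concat(
                [self.params.reset_index(drop=True),
                 pd.DataFrame(self.stats, columns=list(self.stat_names))],
                axis=1,
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        import io

        meta: dict[str, str] = {}
        text = open(path).read().splitlines(keepends=True)
        header_lines = []
        body_start = 0
        for i, line in enumerate(text):
            if line.startswith("#"):
                header_lines.append(line[1:].strip())
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("".join(text[body_start:])), sep="\t")
        for line in header_lines:
            for tok in line.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        stat_cols = [c for c in df.columns if c in STAT_NAMES]
        params = df[[c for c in PARAM_NAMES if c in df.columns]]
        return cls(
            meta.get("model", "?"),
            params,
            df[stat_cols].to_numpy(),
            int(meta["seed"]) if meta.get("seed", "None") != "None" else None,
        )


def simulate_reference_table(
    model_id: str,
    priors: scenarios.PriorSet,
    n_sims: int,
    sample_sizes: dict[str, int],
    rng_seed: int,
    mutation_model: coalsim.MutationModel | None = None,
    fst_kind: str = "phi",
    founder_steps: int = 8,
) -> ReferenceTable:
    """Draw -> simulate -> summarise, ``n_sims`` times.

    Each row gets its own child seed from a spawned ``SeedSequence``,
    so chunked runs concatenate deterministically.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if mutation_model is None:
        mutation_model = coalsim.MutationModel()
    demes = scenarios.default_demes(sample_sizes, priors.modern_ne)
    region_sizes = [sample_sizes.get(r, 0) for r in REGIONS]
    offsets = np.cumsum([0] + region_sizes)
    region_idx = [
        np.arange(offsets[i], offsets[i + 1], dtype=np.intp) for i in range(3)
    ]
    L = mutation_model.L

    children = np.random.SeedSequence(rng_seed).spawn(n_sims)
    rows = np.empty((n_sims, len(STAT_NAMES)))
    prows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            params = scenarios.draw_parameters(priors, model_id, rng)
            events = scenarios.build_scenario(
                model_id, params, demes, founder_steps
            )
            g = coalsim.simulate_genealogy(demes, events, rng)
            var, _ = coalsim.mutate_to_matrix(g, mutation_model, rng)
            rows[i] = sumstats_from_matrix(var, region_idx, L, fst_kind)
        except coalsim.ScenarioConfigError as exc:
            raise coalsim.ScenarioConfigError(
                f"simulation row {i} (model {model_id}): {exc}"
            ) from exc
        prows.append(
            [params.t0, params.t1, params.anc0, params.anc1,
             params.bot0 if params.bot0 is not None else np.nan,
             params.bot1 if params.bot1 is not None else np.nan]
        )
    return ReferenceTable(
        model_id,
        pd.DataFrame(prows, columns=list(PARAM_NAMES)),
        rows,
        rng_seed,
        priors_desc=(
            f"t0~U({priors.t0.lo:g},{priors.t0.hi:g}) "
            f"t1~U({priors.t1.lo:g},{priors.t1.hi:g}) "
            f"anc~U({priors.anc0.lo:g},{priors.anc0.hi:g}) "
            f"bot~Exp({priors.bot_frac0.mean:g}) "
            f"Ne={priors.modern_ne}"
        ),
    )


# ---------------------------------------------------------------------------
# model selection

@dataclass(frozen=True)
class AbcSettings:
    """Knobs for the ABC stage.

    ``tolerances`` are accepted *fractions* of all simulations (the
    published tolerance levels 0.001-0.01 mean 4,000-40,000 of 4M
    rows).  ``method`` is ``rejection`` or ``neuralnet``; the network
    is a single hidden layer of ``n_hidden`` units with ``weight_decay``
    L2 penalty, refit ``n_restarts`` times keeping the best loss.
    """

    tolerances: tuple = (0.001, 0.002, 0.005, 0.01)
    method: str = "neuralnet"
    n_hidden: int = 10
    weight_decay: float = 0.01
    n_restarts: int = 10
    max_iter: int = 300
    cv_steps: int = 100

    def __post_init__(self):
        if any(not (0 < d <= 1) for d in self.tolerances):
            raise ValueError("tolerances must lie in (0, 1]")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.method not in {"rejection", "neuralnet"}:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ModelSelectionResult:
    """Posterior model probabilities and Bayes factors per tolerance."""

    models: tuple
    posterior: dict  # delta -> {model: PP}
    bayes_factors: dict  # delta -> {(m1, m2): BF}
    n_accepted: dict  # delta -> int

    def best(self, delta) -> str:
        pp = self.posterior[delta]
        return max(pp, key=pp.get)


def _standardise(X: np.ndarray, obs: np.ndarray):
    """MAD-standardise columns; drop zero-MAD columns with a warning."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    keep = mad > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-MAD statistic(s)",
            RuntimeWarning,
            stacklevel=3,
        )
    Xs = (X[:, keep] - med[keep]) / mad[keep]
    return Xs, (obs[keep] - med[keep]) / mad[keep], keep


def _fit_nn_classifier(Xa, ya, obs_s, models_present, settings, rng):
    from sklearn.neural_network import MLPClassifier

    best_model, best_loss = None, np.inf
    for _ in range(max(settings.n_restarts, 1)):
        clf = MLPClassifier(
            hidden_layer_sizes=(settings.n_hidden,),
            alpha=settings.weight_decay,
            solver="lbfgs",
            max_iter=settings.max_iter,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xa, ya)
        if clf.loss_ < best_loss:
            best_model, best_loss = clf, clf.loss_
    proba = best_model.predict_proba(obs_s.reshape(1, -1))[0]
    pp = {m: 0.0 for m in models_present}
    for cls, p in zip(best_model.classes_, proba):
        pp[cls] = float(p)
    return pp


def model_select(
    observed: np.ndarray,
    tables: list[ReferenceTable],
    settings: AbcSettings = AbcSettings(),
    rng_seed: int = 0,
    _exclude: tuple[int, int] | None = None,
) -> ModelSelectionResult:
    """Posterior model probabilities at the observed summary vector.

    ``_exclude=(table_index, row_index)`` removes one row (used by the
    leave-one-out cross-validation).
    """
    models = tuple(t.model_id for t in tables)
    X = np.vstack([t.stats for t in tables])
    y = np.concatenate([[t.model_id] * t.n_sims for t in tables])
    if _exclude is not None:
        ti, ri = _exclude
        offset = sum(t.n_sims for t in tables[:ti]) + ri
        mask = np.ones(X.shape[0], dtype=bool)
        mask[offset] = False
        X, y = X[mask], y[mask]
    total = X.shape[0]
    rng = np.random.default_rng(rng_seed)

    Xs, obs_s, _ = _standardise(X, np.asarray(observed, dtype=float))
    dist = np.sqrt(((Xs - obs_s) ** 2).sum(axis=1))

    posterior: dict = {}
    bayes: dict = {}
    n_acc: dict = {}
    for delta in settings.tolerances:
        k = max(int(round(delta * total)), 1)
        acc = np.argpartition(dist, k - 1)[:k]
        ya = y[acc]
        freq = {m: float(np.mean(ya == m)) for m in models}
        if settings.method == "rejection" or len(set(ya)) == 1:
            if settings.method == "neuralnet" and len(set(ya)) == 1:
                warnings.warn(
                    f"all accepted rows from {ya[0]} at delta={delta}; "
                    "posterior degenerates to 1/0",
                    RuntimeWarning,
                )
            pp = freq
        else:
            pp = _fit_nn_classifier(
                Xs[acc], ya, obs_s, models, settings, rng
            )
        s = sum(pp.values())
        pp = {m: v / s for m, v in pp.items()}
        posterior[delta] = pp
        n_acc[delta] = k
        bf = {}
        for m1 in models:
            for m2 in models:
                if m1 != m2:
                    bf[(m1, m2)] = (
                        pp[m1] / pp[m2] if pp[m2] > 0 else math.inf
                    )
        bayes[delta] = bf
    return ModelSelectionResult(models, posterior, bayes, n_acc)


# ---------------------------------------------------------------------------
# parameter estimation

@dataclass
class ParamPosterior:
    """Adjusted posterior summaries per parameter and tolerance."""

    model_id: str
    estimates: dict  # delta -> {param: {"median", "mean", "mode"}}
    samples: dict  # delta -> DataFrame of adjusted draws (+ "weight")
    n_dropped: dict


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def _weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    from scipy.stats import gaussian_kde

    if np.allclose(x, x[0]):
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman", weights=w)
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_parameters(
    observed: np.ndarray,
    table: ReferenceTable,
    settings: AbcSettings = AbcSettings(),
    rng_seed: int = 0,
) -> ParamPosterior:
    """Regression-adjusted parameter posteriors for one model's table.

    Strictly positive parameters are adjusted on the log scale and
    back-transformed.  Weights are Epanechnikov in the acceptance
    distance.  With ``method='rejection'`` (or ``max_iter=0``) the
    unadjusted accepted draws are summarised directly.
    """
    from sklearn.neural_network import MLPRegressor

    rng = np.random.default_rng(rng_seed)
    pnames = [
        p for p in PARAM_NAMES if p in table.params.columns
        and not table.params[p].isna().all()
    ]
    theta = table.params[pnames].to_numpy(dtype=float)
    X = table.stats
    total = X.shape[0]
    Xs, obs_s, _ = _standardise(X, np.asarray(observed, dtype=float))
    dist = np.sqrt(((Xs - obs_s) ** 2).sum(axis=1))

    estimates: dict = {}
    samples: dict = {}
    n_dropped: dict = {}
    for delta in settings.tolerances:
        k = max(int(round(delta * total)), 2)
        acc = np.argsort(dist)[:k]
        d_acc = dist[acc]
        d_max = d_acc.max() if d_acc.max() > 0 else 1.0
        w = 1.0 - (d_acc / d_max) ** 2
        w = np.clip(w, 1e-12, None)
        log_theta = np.log(theta[acc])

        adjust = settings.method == "neuralnet" and settings.max_iter > 0
        if adjust:
            best, best_loss = None, np.inf
            for _ in range(max(settings.n_restarts, 1)):
                reg = MLPRegressor(
                    hidden_layer_sizes=(settings.n_hidden,),
                    alpha=settings.weight_decay,
                    solver="lbfgs",
                    max_iter=settings.max_iter,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    reg.fit(Xs[acc], log_theta)
                if reg.loss_ < best_loss:
                    best, best_loss = reg, reg.loss_
            pred_obs = best.predict(obs_s.reshape(1, -1))[0]
            pred_acc = best.predict(Xs[acc])
            adj = pred_obs + (log_theta - pred_acc)
        else:
            adj = log_theta
        vals = np.exp(adj)
        finite = np.isfinite(vals).all(axis=1)
        n_dropped[delta] = int((~finite).sum())
        vals, wv = vals[finite], w[finite]
        wv = wv / wv.sum()
        est = {}
        for j, p in enumerate(pnames):
            est[p] = {
                "median": _weighted_median(vals[:, j], wv),
                "mean": float(np.average(vals[:, j], weights=wv)),
                "mode": _weighted_mode(vals[:, j], wv),
            }
        estimates[delta] = est
        df = pd.DataFrame(vals, columns=pnames)
        df["weight"] = wv
        samples[delta] = df
    return ParamPosterior(table.model_id, estimates, samples, n_dropped)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CrossValidationResult:
    """Confusion matrices and percent-correct per tolerance level."""

    models: tuple
    confusion: dict  # delta -> DataFrame true x assigned
    pct_correct: dict  # delta -> {model: %}
    mean_pct: float


def cross_validate(
    tables: list[ReferenceTable],
    settings: AbcSettings = AbcSettings(),
    cv_steps: int = 100,
    rng_seed: int = 0,
) -> CrossValidationResult:
    """Leave-one-out model-choice cross-validation.

    For each model, ``cv_steps`` table rows serve as pseudo-observed
    datasets; each is classified against all tables with itself
    removed.  Percent correct is reported per model and tolerance; the
    headline number is the average over both.
    """
    if cv_steps < 1:
        raise ValueError("cv_steps must be >= 1")
    for t in tables:
        if cv_steps > t.n_sims:
            raise ValueError(
                f"cv_steps={cv_steps} exceeds table size {t.n_sims} "
                f"({t.model_id})"
            )
    models = tuple(t.model_id for t in tables)
    rng = np.random.default_rng(rng_seed)
    confusion = {
        d: pd.DataFrame(0, index=list(models), columns=list(models))
        for d in settings.tolerances
    }
    for ti, t in enumerate(tables):
        pick = rng.choice(t.n_sims, size=cv_steps, replace=False)
        for ri in pick:
            res = model_select(
                t.stats[ri],
                tables,
                settings,
                rng_seed=int(rng.integers(2**31 - 1)),
                _exclude=(ti, int(ri)),
            )
            for d in settings.tolerances:
                confusion[d].loc[t.model_id, res.best(d)] += 1
    pct = {
        d: {
            m: 100.0 * confusion[d].loc[m, m] / cv_steps for m in models
        }
        for d in settings.tolerances
    }
    mean_pct = float(
        np.mean([v for d in settings.tolerances for v in pct[d].values()])
    )
    return CrossValidationResult(models, confusion, pct, mean_pct)
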