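"""Per-deme diversity statistics, neutrality tests and mismatch fitting.

Implements the classical mtDNA summary panel: segregating sites S, mean
pairwise differences k, nucleotide diversity pi = k / L, haplotype
diversity H (unbiased), Tajima's D, Fu's F_S (via the exact Ewens
sampling probability of the observed haplotype count with theta-hat =
k), and the Ramos-Onsins & Rozas R2 statistic.  pi and k use raw
nucleotide differences without substitution-model correction, the
convention of Arlequin/DnaSP for these estimators; model-corrected
distances belong to the structure module.

P-values for D and R2 come from neutral constant-size coalescent
simulations conditioned on the sample size and the observed number of
segregating sites (mutations placed on branches proportionally to
length); the p-value for F_S comes from simulations with theta set to
the observed k.  All are seedable.  The beta approximation to the null
distribution of D is available as a cross-check only.

The mismatch module fits the sudden-expansion model: the expected
distribution of pairwise differences j after an instantaneous change
from theta0 to theta1 at tau = 2*u*t mutational units is the Poisson
smearing of the equilibrium geometric distributions,

    F_j(tau, theta0, theta1) = F^eq_j(theta1)
        + exp(-tau (theta1 + 1) / theta1)
          * sum_{i<=j} tau^(j-i)/(j-i)! [F^eq_i(theta0) - F^eq_i(theta1)]

with F^eq_j(theta) = theta^j / (theta+1)^(j+1).  The fit minimises the
sum of squared deviations (SSD) between observed and expected mismatch
frequencies with theta1 capped at 99999; SSD and Harpending's
raggedness get parametric-bootstrap p-values (simulate under the fitted
expansion, refit, compare).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .alignment import Alignment
from . import coalsim

__all__ = [
    "DiversityStats",
    "MismatchFit",
    "diversity_stats",
    "mismatch_fit",
    "tajimas_d",
    "fu_fs",
    "r2_statistic",
    "pairwise_difference_counts",
    "log_ewens_tail",
]


# ---------------------------------------------------------------------------
# core statistics on integer-coded matrices (no missing data)

def _allele_counts(m: np.ndarray) -> np.ndarray:
    """4 x L counts of each base per column."""
    return np.stack([(m == a).sum(axis=0) for a in range(4)])


def segregating_sites(m: np.ndarray) -> int:
    if m.shape[1] == 0:
        return 0
    return int((m != m[0]).any(axis=0).sum())


def mean_pairwise_differences(m: np.ndarray) -> float:
    """k: average number of differing sites over all sequence pairs."""
    n = m.shape[0]
    if n < 2:
        return 0.0
    c = _allele_counts(m)
    same = (c * (c - 1) // 2).sum()
    pairs = n * (n - 1) // 2
    return float(pairs * m.shape[1] - same) / pairs


def haplotype_counts(m: np.ndarray) -> np.ndarray:
    """Multiplicity of each distinct row."""
    if m.shape[1] == 0:
        return np.array([m.shape[0]])
    _, counts = np.unique(
        np.ascontiguousarray(m).view([("", m.dtype)] * m.shape[1]),
        return_counts=True,
    )
    return counts


def haplotype_diversity(m: np.ndarray) -> tuple[float, float]:
    """Unbiased gene diversity H = n/(n-1) (1 - sum p_i^2) and its SD.

    The variance is Nei's (1987) large-sample formula.
    """
    n = m.shape[0]
    counts = haplotype_counts(m)
    p = counts / n
    s2 = float((p**2).sum())
    if n < 2:
        return 0.0, 0.0
    H = n / (n - 1) * (1.0 - s2)
    s3 = float((p**3).sum())
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    )
    return H, math.sqrt(max(var, 0.0))


def pairwise_difference_counts(m: np.ndarray) -> np.ndarray:
    """Histogram of pairwise difference counts 0..max (the mismatch data)."""
    n = m.shape[0]
    diffs = []
    for i in range(n - 1):
        diffs.append((m[i + 1:] != m[i]).sum(axis=1))
    d = np.concatenate(diffs) if diffs else np.array([], dtype=int)
    return np.bincount(d) if d.size else np.array([n * (n - 1) // 2 or 0])


def _tajima_constants(n: int) -> dict:
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def tajimas_d(n: int, S: int, k: float) -> float:
    """Tajima's (1989) D from sample size, segregating sites and k."""
    if n < 4 or S == 0:
        return math.nan
    c = _tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    return (k - S / c["a1"]) / denom


# Tajima's (1983) total variance of k under no recombination,
# b1*k + b2*k^2, used for the printed "+/- SD" of k; SD(pi) = SD(k)/L.
def k_standard_deviation(n: int, k: float) -> float:
    if n < 2:
        return 0.0
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1))
    return math.sqrt(max(b1 * k + b2 * k**2, 0.0))


# ---------------------------------------------------------------------------
# Fu's F_S via the Ewens sampling formula

def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = -np.inf
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        new[1 : m + 2] = np.logaddexp(
            math.log(m) + row[1 : m + 2], np.concatenate(([-np.inf], row[1 : m + 1]))
        )
        row = new
    return row


def log_ewens_tail(n: int, k0: int, theta: float) -> float:
    """log P(K >= k0) for the Ewens haplotype-count distribution.

    P(K = k) = |s(n,k)| theta^k / theta^(n) (rising factorial).
    """
    if theta <= 0:
        return 0.0 if k0 <= 1 else -np.inf
    logs = _log_stirling_row(n)
    ks = np.arange(1, n + 1)
    logp = logs[1:] + ks * math.log(theta)
    logp -= special.gammaln(theta + n) - special.gammaln(theta)
    tail = special.logsumexp(logp[ks >= k0])
    return float(min(tail, 0.0))


def fu_fs(n: int, k: float, n_hap: int) -> float:
    """Fu's (1997) F_S with theta-hat = k.

    F_S = ln(S' / (1 - S')) with S' = P(K >= observed haplotype count)
    under the Ewens distribution at theta = k.
    """
    if k <= 0 or n < 2:
        return math.nan
    log_sp = log_ewens_tail(n, n_hap, k)
    if log_sp >= 0.0:  # S' = 1: every sample has >= n_hap haplotypes
        return math.inf
    log_1m = special.log1p(-math.exp(log_sp)) if log_sp < -1e-12 else -np.inf
    return float(log_sp - log_1m)


def r2_statistic(m: np.ndarray) -> float:
    """Ramos-Onsins & Rozas (2002) R2 from singleton counts per sequence."""
    n, L = m.shape
    S = segregating_sites(m)
    if S == 0 or n < 2:
        return math.nan
    k = mean_pairwise_differences(m)
    U = np.zeros(n)
    for col in range(L):
        vals, counts = np.unique(m[:, col], return_counts=True)
        if vals.size < 2:
            continue
        for v, c in zip(vals, counts):
            if c == 1:
                U[np.argmax(m[:, col] == v)] += 1
    return float(math.sqrt(((U - k / 2.0) ** 2).mean()) / S)


# ---------------------------------------------------------------------------
# null-model simulation machinery

def _kingman_tree(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and derived-carrier leaf sets for a neutral genealogy.

    Time in units of N generations (rate 1 per pair).  Returns
    (lengths, leaf boolean matrix) over the 2n-2 non-root branches.
    """
    g = coalsim.simulate_genealogy(
        [coalsim.DemeConfig("d", 1.0, n)], [], rng
    )
    bl = g.branch_lengths()[:-1]
    leaves = g.leaves_under()
    carrier = np.zeros((2 * n - 2, n), dtype=bool)
    for node in range(2 * n - 2):
        carrier[node, leaves[node]] = True
    return bl, carrier


def _null_fixed_s(n: int, S: int, n_reps: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """(D, R2) samples under neutrality conditioned on n and S."""
    Ds = np.empty(n_reps)
    R2s = np.empty(n_reps)
    pairs = n * (n - 1) / 2.0
    for r in range(n_reps):
        bl, carrier = _kingman_tree(n, rng)
        branch = rng.choice(bl.size, size=S, p=bl / bl.sum())
        sizes = carrier[branch].sum(axis=1)
        k = float((sizes * (n - sizes)).sum() / pairs)
        Ds[r] = tajimas_d(n, S, k)
        U = np.zeros(n)
        for b, c in zip(branch, sizes):
            if c == 1:
                U[np.argmax(carrier[b])] += 1
            elif c == n - 1:
                U[np.argmin(carrier[b])] += 1
        R2s[r] = math.sqrt(((U - k / 2.0) ** 2).mean()) / S
    return Ds, R2s


def _null_fs(n: int, theta: float, n_reps: int, rng) -> np.ndarray:
    """F_S samples under neutrality at fixed theta (infinite sites)."""
    out = np.empty(n_reps)
    pairs = n * (n - 1) / 2.0
    for r in range(n_reps):
        bl, carrier = _kingman_tree(n, rng)
        n_mut = rng.poisson(theta / 2.0 * bl.sum())
        if n_mut == 0:
            out[r] = math.nan
            continue
        branch = rng.choice(bl.size, size=n_mut, p=bl / bl.sum())
        sizes = carrier[branch].sum(axis=1)
        k = float((sizes * (n - sizes)).sum() / pairs)
        # haplotype = set of mutated branches above each leaf
        key = np.zeros(n, dtype=np.uint64)
        mixer = rng.integers(1, 2**63, size=n_mut, dtype=np.uint64)
        for b, h in zip(branch, mixer):
            key[carrier[b]] ^= h
        n_hap = np.unique(key).size
        out[r] = fu_fs(n, k, n_hap) if k > 0 else math.nan
    return out


def tajimas_d_beta_pvalue(n: int, D: float) -> float:
    """Two-tailed p-value from Tajima's beta approximation (cross-check)."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    Dmin = (2.0 / n - 1.0 / a1) / math.sqrt(_tajima_constants(n)["e2"])
    Dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(_tajima_constants(n)["e2"])
    alpha = -(1.0 + Dmin * Dmax) * Dmax / (Dmax - Dmin)
    beta = (1.0 + Dmin * Dmax) * Dmin / (Dmax - Dmin)
    x = (D - Dmin) / (Dmax - Dmin)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2.0 * min(cdf, 1.0 - cdf))


# ---------------------------------------------------------------------------
# public per-deme statistics

@dataclass
class DiversityStats:
    """One deme's row of the diversity / neutrality table."""

    deme: str
    n: int
    hap: int
    pi: float
    pi_sd: float
    H: float
    H_sd: float
    k: float
    k_sd: float
    S: int
    D: float
    D_p: float
    Fs: float
    Fs_p: float
    R2: float
    R2_p: float

    @property
    def d_defined(self) -> bool:
        return not math.isnan(self.D)


def diversity_stats(
    a: Alignment,
    deme: str,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    deletion: str = "complete",
) -> DiversityStats:
    """All per-deme summary and neutrality statistics.

    ``n_perm`` is the number of null coalescent simulations behind the
    D, F_S and R2 p-values (10,000 by default).  Statistics that are
    undefined at S = 0 (D, R2) are reported as NaN, not zero.
    """
    keep = a.analysed_sites(deletion)
    sub = a.subset(deme)
    m = sub.matrix()[:, keep[: a.L]]
    n = sub.n
    if n < 2:
        raise ValueError(f"deme {deme!r} needs >= 2 sequences")
    L_eff = int(keep.sum())
    rng = np.random.default_rng(rng_seed)

    S = segregating_sites(m)
    k = mean_pairwise_differences(m)
    pi = k / L_eff if L_eff else 0.0
    H, H_sd = haplotype_diversity(m)
    hap = haplotype_counts(m).size
    k_sd = k_standard_deviation(n, k)
    pi_sd = k_sd / L_eff if L_eff else 0.0

    D = tajimas_d(n, S, k)
    Fs = fu_fs(n, k, hap)
    R2 = r2_statistic(m)

    D_p = Fs_p = R2_p = math.nan
    if S > 0 and n >= 4:
        Dn, R2n = _null_fixed_s(n, S, n_perm, rng)
        # two-sided for D (extreme in either direction), one-sided low for R2
        D_p = float(np.mean(np.abs(Dn) >= abs(D)))
        R2_p = float(np.mean(R2n <= R2))
    if k > 0 and not math.isnan(Fs):
        Fn = _null_fs(n, k, n_perm, rng)
        Fs_p = float(np.nanmean(Fn <= Fs))

    return DiversityStats(
        deme, n, hap, pi, pi_sd, H, H_sd, k, k_sd, S, D, D_p, Fs, Fs_p, R2, R2_p
    )


def diversity_table(a: Alignment, n_perm: int = 10_000, rng_seed: int = 0):
    """DataFrame with one DiversityStats row per deme."""
    import pandas as pd

    rows = []
    for i, d in enumerate(a.demes):
        st = diversity_stats(a, d, n_perm=n_perm, rng_seed=rng_seed + i)
        rows.append(vars(st))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mismatch distribution / sudden-expansion model

def expected_mismatch(
    tau: float, theta0: float, theta1: float, jmax: int
) -> np.ndarray:
    """Expected mismatch probabilities F_0..F_jmax under sudden expansion."""
    j = np.arange(jmax + 1)

    def eq(theta):
        if theta <= 0:
            out = np.zeros(jmax + 1)
            out[0] = 1.0
            return out
        return np.exp(j * math.log(theta) - (j + 1) * math.log1p(theta))

    f0, f1 = eq(theta0), eq(theta1)
    if tau <= 0:
        return f0
    diff = f0 - f1
    log_pois = j * math.log(tau) - special.gammaln(j + 1) if tau > 0 else None
    conv = np.array(
        [np.sum(np.exp(log_pois[: jj + 1][::-1]) * diff[: jj + 1]) for jj in j]
    )
    damp = math.exp(-tau * (theta1 + 1.0) / theta1) if theta1 > 0 else math.exp(-tau)
    # cancellation in the convolution can leave O(1e-17) negatives
    return np.maximum(f1 + damp * conv, 0.0)


@dataclass
class MismatchFit:
    """Sudden-expansion fit to one deme's mismatch distribution."""

    deme: str
    histogram: np.ndarray
    tau: float
    theta0: float
    theta1: float
    SSD: float
    SSD_p: float
    raggedness: float
    raggedness_p: float


def harpending_raggedness(freqs: np.ndarray) -> float:
    """Harpending's r: sum of squared successive differences of the
    (relative) mismatch frequencies, including the step past the last class."""
    x = np.concatenate((freqs, [0.0]))
    return float(((x[1:] - x[:-1]) ** 2).sum())


def _ssd(obs_freq: np.ndarray, params) -> float:
    exp = expected_mismatch(params[0], params[1], params[2], obs_freq.size - 1)
    return float(((obs_freq - exp) ** 2).sum())


def fit_expansion(histogram: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares (SSD) fit of (tau, theta0, theta1); theta1 <= 99999.

    Multi-start bounded Nelder-Mead; among near-equal optima the
    smallest tau wins.
    """
    total = histogram.sum()
    obs = histogram / total if total else histogram.astype(float)
    jmax = histogram.size - 1
    mean_d = float(np.arange(jmax + 1) @ obs)
    if mean_d == 0.0:
        return 0.0, 0.0, 0.0, 0.0

    cap = 99_999.0
    starts = []
    for tau0 in (0.5 * mean_d, mean_d, 2.0 * mean_d):
        for th0 in (0.01, max(0.1, 0.1 * mean_d)):
            starts.append((tau0, th0, cap / 10.0))
            starts.append((tau0, th0, 5.0 * mean_d))
    best = None
    bounds = [(0.0, 3.0 * (jmax + 1)), (0.0, 50.0), (0.0, cap)]

    def objective(x):
        tau, th0, th1 = x
        if th1 < th0:  # expansion constraint theta0 <= theta1
            return 1e6 + (th0 - th1)
        return _ssd(obs, (tau, th0, th1))

    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            bounds=bounds, options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 2000},
        )
        cand = (res.fun, res.x[0], res.x[1], res.x[2])
        if best is None or cand[0] < best[0] - 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
        ):
            best = cand
    ssd, tau, th0, th1 = best
    return float(tau), float(th0), float(min(th1, cap)), float(ssd)


def mismatch_fit(
    a: Alignment,
    deme: str,
    n_boot: int = 200,
    rng_seed: int = 0,
    deletion: str = "complete",
) -> MismatchFit:
    """Fit the sudden-expansion model and bootstrap SSD / raggedness p-values.

    The parametric bootstrap simulates ``n_boot`` coalescent samples
    under the fitted expansion (instantaneous growth from theta0 to
    theta1 at tau mutational units ago, infinite sites), refits each,
    and reports the fraction of simulated statistics at least as large
    as the observed ones.
    """
    keep = a.analysed_sites(deletion)
    sub = a.subset(deme)
    m = sub.matrix()[:, keep[: a.L]]
    n = sub.n
    if n < 3:
        raise ValueError(f"deme {deme!r} needs >= 3 sequences for a mismatch fit")

    hist = pairwise_difference_counts(m)
    total = hist.sum()
    obs_freq = hist / total
    tau, th0, th1, ssd = fit_expansion(hist)
    rag = harpending_raggedness(obs_freq)
    if tau == 0.0 and ssd == 0.0:
        return MismatchFit(deme, hist, 0.0, th0, th1, 0.0, 1.0, rag, 1.0)

    rng = np.random.default_rng(rng_seed)
    mu = 1e-3  # arbitrary bookkeeping rate; only theta products matter
    N1 = th1 / (2.0 * mu) if th1 > 0 else 0.5 / (2.0 * mu)
    N0 = max(th0, 1e-3) / (2.0 * mu)
    t_exp = tau / (2.0 * mu)
    ssd_sim = np.empty(n_boot)
    rag_sim = np.empty(n_boot)
    L_model = max(10 * (hist.size + 5), 1000)
    for b in range(n_boot):
        g = coalsim.simulate_genealogy(
            [coalsim.DemeConfig("d", N1, n)],
            [coalsim.Resize(t_exp, "d", N0)],
            rng,
        )
        mm = coalsim.MutationModel(mu_locus=mu, L=L_model, kind="infinite_sites")
        try:
            var, _ = coalsim.mutate_to_matrix(g, mm, rng)
        except ValueError:  # more mutations than sites: enlarge locus
            mm = coalsim.MutationModel(mu_locus=mu, L=10 * L_model,
                                       kind="infinite_sites")
            var, _ = coalsim.mutate_to_matrix(g, mm, rng)
        h = pairwise_difference_counts(var)
        _, _, _, ssd_b = fit_expansion(h)
        ssd_sim[b] = ssd_b
        rag_sim[b] = harpending_raggedness(h / h.sum())
    SSD_p = float((np.sum(ssd_sim >= ssd) + 1) / (n_boot + 1))
    rag_p = float((np.sum(rag_sim >= rag) + 1) / (n_boot + 1))
    return MismatchFit(deme, hist, tau, th0, th1, ssd, SSD_p, rag, rag_p)
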