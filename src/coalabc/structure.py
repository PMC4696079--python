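"""Population structure: model-corrected distances, Phi_ST, AMOVA, SAMOVA.

AMOVA follows Excoffier, Smouse & Quattro (1992): pairwise molecular
distances between sequences are treated as squared Euclidean distances,
sums of squares are partitioned hierarchically (among groups / among
populations within groups / within populations), and fixation indices
are ratios of the resulting variance components.  Negative components
are retained, not truncated.  Permutation tests shuffle the appropriate
units per level (individuals among populations for F_ST and Phi_ST,
individuals among populations within groups for F_SC, whole populations
among groups for F_CT); p-values use the (count + 1)/(n_perm + 1)
convention.

SAMOVA searches population groupings that maximise F_CT, either by
exhaustive enumeration of set partitions (feasible through ~10 demes)
or by seeded simulated annealing; no geographic-contiguity constraint
is imposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment

__all__ = [
    "DistanceModel",
    "PhiStMatrix",
    "AmovaResult",
    "SamovaResult",
    "distance_matrix",
    "pairwise_phi_st",
    "amova",
    "samova",
]


@dataclass(frozen=True)
class DistanceModel:
    """Substitution model for inter-sequence distances.

    ``name`` is one of ``p`` (raw proportion of differing sites),
    ``jc69``, ``k2p`` or ``tn93``; ``gamma_alpha`` adds gamma-distributed
    rate heterogeneity to the correction.
    """

    name: str = "tn93"
    gamma_alpha: float | None = None

    def __post_init__(self):
        if self.name not in {"p", "jc69", "k2p", "tn93"}:
            raise ValueError(f"unknown distance model {self.name!r}")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be positive")


def _gamma_log(x: np.ndarray, alpha: float | None) -> np.ndarray:
    """-log(x), or its gamma-rates analogue alpha*(x^(-1/alpha) - 1)."""
    if alpha is None:
        return -np.log(x)
    return alpha * (np.power(x, -1.0 / alpha) - 1.0)


def distance_matrix(
    a: Alignment, model: DistanceModel = DistanceModel(), deletion: str = "complete"
) -> np.ndarray:
    """Symmetric n x n matrix of model-corrected distances.

    Saturated pairs whose correction is undefined (logarithm of a
    non-positive quantity) fall back to the p-distance and are flagged
    via the returned matrix's ``saturated`` attribute-free convention:
    a warning is emitted instead.
    """
    keep = a.analysed_sites(deletion)
    m = a.matrix()[:, keep]
    n, L = m.shape
    if L == 0:
        raise ValueError("no sites left after deletion policy")
    alpha = model.gamma_alpha

    eq = m[:, None, :] == m[None, :, :]
    if deletion == "pairwise":
        valid = (m[:, None, :] >= 0) & (m[None, :, :] >= 0)
    else:
        valid = np.ones_like(eq)
    n_valid = valid.sum(axis=2).astype(float)
    n_valid[n_valid == 0] = np.nan
    p = ((~eq) & valid).sum(axis=2) / n_valid

    if model.name == "p":
        d = p
    elif model.name == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        d = np.where(arg > 0, 0.75 * _gamma_log(np.clip(arg, 1e-12, None), alpha), np.nan)
    else:
        purine = (m == 0) | (m == 2)
        # transitions within purines / pyrimidines, and transversions
        both_pur = purine[:, None, :] & purine[None, :, :]
        both_pyr = ~purine[:, None, :] & ~purine[None, :, :]
        diff = (~eq) & valid
        P1 = (diff & both_pur).sum(axis=2) / n_valid  # A<->G
        P2 = (diff & both_pyr).sum(axis=2) / n_valid  # C<->T
        Q = p - P1 - P2
        if model.name == "k2p":
            P = P1 + P2
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            ok = (w1 > 0) & (w2 > 0)
            d = np.where(
                ok,
                0.5 * _gamma_log(np.clip(w1, 1e-12, None), alpha)
                + 0.25 * _gamma_log(np.clip(w2, 1e-12, None), alpha),
                np.nan,
            )
        else:  # tn93
            counts = np.stack([(m == b).sum(axis=1) for b in range(4)]).T  # n x 4
            f = counts.sum(axis=0) / counts.sum()
            gA, gC, gG, gT = f
            gR, gY = gA + gG, gC + gT
            if min(gA, gC, gG, gT) <= 0:
                # a base absent entirely: degenerate for TN93; use jc69 path
                return distance_matrix(
                    a, DistanceModel("jc69", model.gamma_alpha), deletion
                )
            k1 = 2.0 * gA * gG / gR
            k2 = 2.0 * gT * gC / gY
            k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
            w1 = 1.0 - P1 / k1 - Q / (2.0 * gR)
            w2 = 1.0 - P2 / k2 - Q / (2.0 * gY)
            w3 = 1.0 - Q / (2.0 * gR * gY)
            ok = (w1 > 0) & (w2 > 0) & (w3 > 0)
            d = np.where(
                ok,
                k1 * _gamma_log(np.clip(w1, 1e-12, None), alpha)
                + k2 * _gamma_log(np.clip(w2, 1e-12, None), alpha)
                + k3 * _gamma_log(np.clip(w3, 1e-12, None), alpha),
                np.nan,
            )

    bad = np.isnan(d)
    np.fill_diagonal(bad, False)
    if bad.any():
        import warnings

        warnings.warn(
            f"{int(bad.sum() // 2)} saturated pairs: fell back to p-distance",
            RuntimeWarning,
            stacklevel=2,
        )
        d = np.where(bad, p, d)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


# ---------------------------------------------------------------------------
# AMOVA machinery.  Distances enter as squared Euclidean distances
# (delta^2); SS over a set of sequences = sum of delta^2 over its pairs
# divided by the set size.

def _ss(d2: np.ndarray, idx: np.ndarray) -> float:
    if idx.size < 2:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * idx.size))


def _amova_components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray
) -> dict:
    """Variance components for a two- or three-level hierarchy.

    ``pop_of`` maps sequence -> population index, ``group_of_pop`` maps
    population -> group index.
    """
    N = d2.shape[0]
    pops = np.unique(pop_of)
    P = pops.size
    groups = np.unique(group_of_pop)
    G = groups.size
    n_p = np.array([(pop_of == p).sum() for p in pops], dtype=float)

    ss_total = _ss(d2, np.arange(N))
    ss_wp = sum(_ss(d2, np.where(pop_of == p)[0]) for p in pops)
    ss_wg = sum(
        _ss(d2, np.where(np.isin(pop_of, pops[group_of_pop == g]))[0])
        for g in groups
    )
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp  # among populations within groups

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0

    N_g = np.array([n_p[group_of_pop == g].sum() for g in groups])
    sum_np2_over_Ng = sum(
        (n_p[group_of_pop == g] ** 2).sum() / N_g[i] for i, g in enumerate(groups)
    )
    if G > 1:
        n_coef = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else np.nan
        n_prime = (sum_np2_over_Ng - (n_p**2).sum() / N) / df_ag
        n_dprime = (N - (N_g**2).sum() / N) / df_ag
        sigma_b = ((ss_ap / df_ap) - sigma_c) / n_coef if df_ap > 0 else 0.0
        sigma_a = ((ss_ag / df_ag) - sigma_c - n_prime * sigma_b) / n_dprime
    else:
        n_coef = (N - (n_p**2).sum() / N) / df_ap
        sigma_b = ((ss_ap / df_ap) - sigma_c) / n_coef
        sigma_a = math.nan
    return {
        "sigma_a": sigma_a,
        "sigma_b": sigma_b,
        "sigma_c": sigma_c,
        "ss": (ss_ag, ss_ap, ss_wp, ss_total),
        "df": (df_ag, df_ap, df_wp),
    }


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition and fixation indices."""

    F_CT: float
    F_SC: float
    F_ST: float
    variance_components: tuple[float, float, float]  # among-group, among-pop, within
    percentages: tuple[float, float, float]
    p_values: dict = field(default_factory=dict)


def _indices_from_components(sa: float, sb: float, sc: float):
    if math.isnan(sa):  # single group: one-level AMOVA
        tot = sb + sc
        fst = sb / tot if tot != 0 else math.nan
        return math.nan, math.nan, fst
    tot = sa + sb + sc
    f_ct = sa / tot if tot != 0 else math.nan
    f_sc = sb / (sb + sc) if (sb + sc) != 0 else math.nan
    f_st = (sa + sb) / tot if tot != 0 else math.nan
    return f_ct, f_sc, f_st


def amova(
    a: Alignment,
    grouping: dict[str, str] | None = None,
    model: DistanceModel = DistanceModel(),
    n_perm: int = 1000,
    rng_seed: int = 0,
    d2: np.ndarray | None = None,
) -> AmovaResult:
    """AMOVA over demes (optionally nested in groups).

    With ``grouping=None`` (or a single group) a one-level AMOVA is
    computed and F_CT/F_SC are undefined (NaN).  A precomputed squared
    distance matrix may be passed via ``d2`` to skip the model step.
    """
    demes = a.demes
    if grouping is None:
        grouping = {d: "all" for d in demes}
    missing = [d for d in demes if d not in grouping]
    if missing:
        raise KeyError(f"grouping omits demes: {missing}")
    if d2 is None:
        d2 = distance_matrix(a, model)
    labels = a.deme_labels
    pop_names = demes
    pop_index = {d: i for i, d in enumerate(pop_names)}
    pop_of = np.array([pop_index[x] for x in labels])
    group_names = sorted({grouping[d] for d in demes})
    gi = {g: i for i, g in enumerate(group_names)}
    group_of_pop = np.array([gi[grouping[d]] for d in pop_names])

    comp = _amova_components(d2, pop_of, group_of_pop)
    sa, sb, sc = comp["sigma_a"], comp["sigma_b"], comp["sigma_c"]
    f_ct, f_sc, f_st = _indices_from_components(sa, sb, sc)
    if math.isnan(sa):
        comps = (0.0, sb, sc)
    else:
        comps = (sa, sb, sc)
    tot = sum(comps)
    pct = tuple(100.0 * c / tot for c in comps) if tot != 0 else (np.nan,) * 3

    pvals: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(rng_seed)
        n = len(labels)
        multi = len(group_names) > 1
        count_st = count_sc = count_ct = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            c1 = _amova_components(d2, pop_of[perm], group_of_pop)
            _, _, f_st_p = _indices_from_components(
                c1["sigma_a"], c1["sigma_b"], c1["sigma_c"]
            )
            if not math.isnan(f_st_p) and f_st_p >= f_st:
                count_st += 1
            if multi:
                # F_SC: permute individuals among pops within groups
                perm2 = np.arange(n)
                for g in range(len(group_names)):
                    members = np.where(group_of_pop[pop_of] == g)[0]
                    perm2[members] = members[rng.permutation(members.size)]
                c2 = _amova_components(d2, pop_of[perm2], group_of_pop)
                f_ct2, f_sc2, _ = _indices_from_components(
                    c2["sigma_a"], c2["sigma_b"], c2["sigma_c"]
                )
                if not math.isnan(f_sc2) and f_sc2 >= f_sc:
                    count_sc += 1
                # F_CT: permute whole populations among groups
                gperm = group_of_pop[rng.permutation(group_of_pop.size)]
                c3 = _amova_components(d2, pop_of, gperm)
                f_ct3, _, _ = _indices_from_components(
                    c3["sigma_a"], c3["sigma_b"], c3["sigma_c"]
                )
                if not math.isnan(f_ct3) and f_ct3 >= f_ct:
                    count_ct += 1
        pvals["F_ST"] = (count_st + 1) / (n_perm + 1)
        if multi:
            pvals["F_SC"] = (count_sc + 1) / (n_perm + 1)
            pvals["F_CT"] = (count_ct + 1) / (n_perm + 1)

    return AmovaResult(f_ct, f_sc, f_st, comps, pct, pvals)


# ---------------------------------------------------------------------------
# pairwise Phi_ST

@dataclass
class PhiStMatrix:
    demes: list[str]
    phi: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    alpha_corrected: float


def _phi_two_groups(d2: np.ndarray, z: np.ndarray, n1: int, n2: int) -> float:
    """Phi_ST for a 2-population split given boolean membership z (pop 1)."""
    N = n1 + n2
    ss_total = d2.sum() / (2.0 * N)
    ss1 = d2[np.ix_(z, z)].sum() / (2.0 * n1)
    ss2 = d2[np.ix_(~z, ~z)].sum() / (2.0 * n2)
    ss_w = ss1 + ss2
    df_a, df_w = 1, N - 2
    sigma_c = ss_w / df_w
    n_coef = (N - (n1 * n1 + n2 * n2) / N) / df_a
    sigma_b = ((ss_total - ss_w) / df_a - sigma_c) / n_coef
    tot = sigma_b + sigma_c
    return sigma_b / tot if tot != 0 else math.nan


def pairwise_phi_st(
    a: Alignment,
    model: DistanceModel = DistanceModel(),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> PhiStMatrix:
    """Pairwise Phi_ST with permutation p-values and Bonferroni correction.

    For each deme pair, individuals are shuffled between the two demes
    ``n_perm`` times; the p-value is the fraction of permuted Phi_ST at
    least as large as observed.  Bonferroni divides ``alpha`` by the
    number of pairs actually tested.
    """
    demes = a.demes
    if len(demes) < 2:
        raise ValueError("need >= 2 demes")
    sizes = {d: sum(1 for x in a.deme_labels if x == d) for d in demes}
    small = [d for d, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"demes with < 2 sequences: {small}")
    d2_full = distance_matrix(a, model)
    labels = np.array(a.deme_labels)
    rng = np.random.default_rng(rng_seed)

    P = len(demes)
    phi = np.zeros((P, P))
    pv = np.ones((P, P))
    n_pairs = P * (P - 1) // 2
    for i, j in itertools.combinations(range(P), 2):
        idx = np.where((labels == demes[i]) | (labels == demes[j]))[0]
        d2 = d2_full[np.ix_(idx, idx)]
        z = labels[idx] == demes[i]
        n1, n2 = int(z.sum()), int((~z).sum())
        obs = _phi_two_groups(d2, z, n1, n2)
        count = 0
        for _ in range(n_perm):
            zp = np.zeros(n1 + n2, dtype=bool)
            zp[rng.choice(n1 + n2, size=n1, replace=False)] = True
            if _phi_two_groups(d2, zp, n1, n2) >= obs:
                count += 1
        phi[i, j] = phi[j, i] = obs
        pv[i, j] = pv[j, i] = (count + 1) / (n_perm + 1)
    alpha_c = alpha / n_pairs
    sig = pv < alpha_c
    np.fill_diagonal(sig, False)
    return PhiStMatrix(demes, phi, pv, sig, alpha_c)


# ---------------------------------------------------------------------------
# SAMOVA

@dataclass
class SamovaResult:
    K: int
    best_grouping: dict[str, str]
    F_CT: float
    trace: list[tuple[tuple[int, ...], float]]


def _canonical_rgs(assignment: np.ndarray) -> np.ndarray:
    """Relabel groups in order of first appearance (restricted growth)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(assignment)
    for i, g in enumerate(assignment):
        if g not in mapping:
            mapping[g] = len(mapping)
        out[i] = mapping[g]
    return out


def _partitions_rgs(P: int, K: int):
    """All set partitions of P items into exactly K blocks, as
    restricted-growth strings."""
    for assignment in itertools.product(range(K), repeat=P):
        # canonical: block labels appear in order of first use, all K used
        seen: list[int] = []
        ok = True
        for x in assignment:
            if x not in seen:
                if x != len(seen):
                    ok = False
                    break
                seen.append(x)
        if ok and len(seen) == K:
            yield assignment


class _GroupScorer:
    """F_CT evaluation for arbitrary deme partitions in O(P^2).

    Cross-population distance sums are precomputed once; only the
    group-level aggregates depend on the partition.
    """

    def __init__(self, d2: np.ndarray, pop_of: np.ndarray):
        pops = np.unique(pop_of)
        self.P = pops.size
        self.n_p = np.array([(pop_of == p).sum() for p in pops], dtype=float)
        self.N = float(d2.shape[0])
        # T[p, q] = sum of d2 over ordered pairs (i in p, j in q)
        Z = np.stack([(pop_of == p).astype(float) for p in pops])
        self.T = Z @ d2 @ Z.T
        self.ss_total = d2.sum() / (2.0 * self.N)
        self.ss_wp = float(sum(self.T[p, p] / (2.0 * self.n_p[p])
                               for p in range(self.P)))

    def f_ct(self, assignment) -> float:
        assignment = np.asarray(assignment)
        G = assignment.max() + 1
        N, P = self.N, self.P
        df_wp = int(N) - P
        df_ap = P - G
        df_ag = G - 1
        if df_ag < 1 or df_wp < 1:
            return math.nan
        N_g = np.array([self.n_p[assignment == g].sum() for g in range(G)])
        ss_wg = 0.0
        sum_np2_over_Ng = 0.0
        for g in range(G):
            members = np.where(assignment == g)[0]
            ss_wg += self.T[np.ix_(members, members)].sum() / (2.0 * N_g[g])
            sum_np2_over_Ng += (self.n_p[members] ** 2).sum() / N_g[g]
        ss_ag = self.ss_total - ss_wg
        ss_ap = ss_wg - self.ss_wp
        sigma_c = self.ss_wp / df_wp
        n_coef = (N - sum_np2_over_Ng) / df_ap if df_ap > 0 else np.nan
        n_prime = (sum_np2_over_Ng - (self.n_p**2).sum() / N) / df_ag
        n_dprime = (N - (N_g**2).sum() / N) / df_ag
        sigma_b = ((ss_ap / df_ap) - sigma_c) / n_coef if df_ap > 0 else 0.0
        sigma_a = ((ss_ag / df_ag) - sigma_c - n_prime * sigma_b) / n_dprime
        tot = sigma_a + sigma_b + sigma_c
        return float(sigma_a / tot) if tot != 0 else math.nan


def samova(
    a: Alignment,
    K: int,
    model: DistanceModel = DistanceModel(),
    mode: str = "exhaustive",
    rng_seed: int = 0,
    n_steps: int = 10_000,
    t0: float = 1.0,
    cooling: float = 0.95,
    d2: np.ndarray | None = None,
) -> SamovaResult:
    """Find the K-group partition of demes maximising F_CT.

    ``exhaustive`` enumerates every set partition into K non-empty
    groups; ``anneal`` runs seeded simulated annealing (single-deme
    reassignment moves, geometric cooling) and agrees with the
    exhaustive optimum on small instances.
    """
    demes = a.demes
    P = len(demes)
    if not (2 <= K <= P - 1):
        raise ValueError(f"K={K} out of range [2, {P - 1}]")
    if d2 is None:
        d2 = distance_matrix(a, model)
    pop_index = {d: i for i, d in enumerate(demes)}
    pop_of = np.array([pop_index[x] for x in a.deme_labels])
    scorer = _GroupScorer(d2, pop_of)

    trace: list[tuple[tuple[int, ...], float]] = []
    if mode == "exhaustive":
        best, best_f = None, -math.inf
        for assignment in _partitions_rgs(P, K):
            f = scorer.f_ct(assignment)
            trace.append((assignment, f))
            if not math.isnan(f) and f > best_f:
                best, best_f = assignment, f
    elif mode == "anneal":
        rng = np.random.default_rng(rng_seed)
        # start from a random valid assignment using all K groups
        cur = np.array(list(range(K)) + list(rng.integers(0, K, size=P - K)))
        rng.shuffle(cur)
        cur_f = scorer.f_ct(_canonical_rgs(cur))
        best, best_f = tuple(cur), cur_f
        T = t0
        for _ in range(n_steps):
            i = int(rng.integers(P))
            counts = np.bincount(cur, minlength=K)
            if counts[cur[i]] == 1:
                continue  # move would empty a group
            new_g = int(rng.integers(K - 1))
            if new_g >= cur[i]:
                new_g += 1
            prop = cur.copy()
            prop[i] = new_g
            f = scorer.f_ct(_canonical_rgs(prop))
            if math.isnan(f):
                continue
            if f > cur_f or rng.random() < math.exp(min((f - cur_f) / T, 0.0)):
                cur, cur_f = prop, f
                if f > best_f:
                    best, best_f = tuple(prop), f
                    trace.append((best, best_f))
            T *= cooling
    else:
        raise ValueError(f"unknown mode {mode!r}")

    grouping = {d: f"group{best[i] + 1}" for i, d in enumerate(demes)}
    return SamovaResult(K, grouping, float(best_f), trace)
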