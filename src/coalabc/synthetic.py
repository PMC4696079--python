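"""Pseudo-observed datasets with known ground truth.

Emulates the study design this pipeline targets: 188 mtDNA sequences of
a 590 bp locus from 8 sampling sites pooled into 3 regions (MEX, SAL,
PER).  A dataset is one genealogy simulated under a chosen demographic
scenario plus finite-sites mutations; regional samples are then
scattered uniformly over the region's sub-sites (regions are panmictic
in the generating model, mirroring the absence of within-region
structure the scenarios assume).  Every dataset carries a truth sidecar
(model, parameters, seed, layout) that fully determines the FASTA given
the code version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import coalsim, scenarios
from .alignment import Alignment, alignment_from_matrix, write_alignment

__all__ = [
    "DEFAULT_LAYOUT",
    "TruthRecord",
    "generate_dataset",
    "make_fixture_suite",
]

# 8 sampling sites -> 3 regions; sizes follow the study's per-site n.
DEFAULT_LAYOUT = {
    "MEX1": ("MEX", 25),
    "MEX2": ("MEX", 21),
    "MEX3": ("MEX", 24),
    "SAL1": ("SAL", 25),
    "SAL2": ("SAL", 15),
    "SAL3": ("SAL", 31),
    "PER1": ("PER", 20),
    "PER2": ("PER", 27),
}


@dataclass
class TruthRecord:
    """Everything needed to regenerate a synthetic dataset."""

    model_id: str
    params: dict
    rng_seed: int
    layout: dict
    mu_locus: float
    L: int
    mutation_kind: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def region_grouping(layout: dict | None = None) -> dict[str, str]:
    layout = DEFAULT_LAYOUT if layout is None else layout
    return {site: region for site, (region, _) in layout.items()}


def generate_dataset(
    model_id: str,
    params_or_priors,
    rng_seed: int,
    layout: dict | None = None,
    mutation_model: coalsim.MutationModel | None = None,
    ne: dict[str, float] | None = None,
) -> tuple[Alignment, TruthRecord]:
    """Simulate one deme-labelled dataset under a demographic scenario.

    ``params_or_priors`` is either a :class:`scenarios.ScenarioParams`
    (fixed truth) or a :class:`scenarios.PriorSet` (truth drawn from the
    priors).  The returned alignment is labelled by sampling site; pool
    with :func:`region_grouping` to get the 3-region version.
    """
    layout = DEFAULT_LAYOUT if layout is None else layout
    if mutation_model is None:
        mutation_model = coalsim.MutationModel()
    rng = np.random.default_rng(rng_seed)

    region_sizes: dict[str, int] = {}
    for site, (region, size) in layout.items():
        region_sizes[region] = region_sizes.get(region, 0) + size

    if isinstance(params_or_priors, scenarios.PriorSet):
        params = scenarios.draw_parameters(params_or_priors, model_id, rng)
        ne = dict(params_or_priors.modern_ne if ne is None else ne)
    else:
        params = params_or_priors
        ne = dict(scenarios.DEFAULT_NE if ne is None else ne)

    demes = scenarios.default_demes(region_sizes, ne)
    events = scenarios.build_scenario(model_id, params, demes)
    g = coalsim.simulate_genealogy(demes, events, rng)
    a = coalsim.apply_mutations(g, mutation_model, rng)

    # scatter each region's sequences uniformly over its sites
    site_of: dict[str, str] = {}
    labels = np.array(a.deme_labels)
    new_labels = list(a.deme_labels)
    for region in scenarios.REGIONS:
        sites = [s for s, (r, _) in layout.items() if r == region]
        counts = [layout[s][1] for s in sites]
        members = np.where(labels == region)[0]
        pool = np.repeat(sites, counts)
        rng.shuffle(members)
        for idx, site in zip(members, pool):
            new_labels[idx] = site
    ids = [f"{new_labels[i]}_{i:03d}" for i in range(a.n)]
    out = Alignment(ids, list(a.seqs), dict(zip(ids, new_labels)))

    truth = TruthRecord(
        model_id,
        {k: v for k, v in asdict(params).items() if v is not None},
        rng_seed,
        {s: list(v) for s, v in layout.items()},
        mutation_model.mu_locus,
        mutation_model.L,
        mutation_model.kind,
    )
    return out, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixture_suite(out_dir, rng_seed: int = 0) -> dict:
    """Write the cross-module test fixtures; return a checksum manifest.

    Includes hand-sized toy alignments with independently computed
    statistics (recorded in the manifest), degenerate cases, and one
    mid-size dataset per demographic model.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": rng_seed, "fixtures": {}}

    def emit(name: str, aln: Alignment, extra: dict | None = None):
        fa = out / f"{name}.fasta"
        dm = out / f"{name}.demes.tsv"
        write_alignment(aln, fa, dm)
        manifest["fixtures"][name] = {
            "fasta": fa.name,
            "deme_map": dm.name,
            "sha256": _sha256(fa),
            **(extra or {}),
        }

    # toy with hand-computed values: 4 seqs, S=2, all pairs enumerable
    toy = Alignment(
        ["a", "b", "c", "d"],
        ["ACGT", "ACGA", "ACTA", "ACGT"],
        {x: "T1" for x in "abcd"},
    )
    # pairwise diffs: ab=1 ac=2 ad=0 bc=1 bd=1 cd=2 -> k = 7/6
    emit("toy_tajima", toy, {"S": 2, "k": 7.0 / 6.0, "hap": 3})

    ident = Alignment(
        ["x", "y", "z"], ["AAAA"] * 3, {x: "D" for x in "xyz"}
    )
    emit("degenerate_identical", ident, {"S": 0, "hap": 1})

    fixed = Alignment(
        ["p1", "p2", "q1", "q2"],
        ["AAAAA", "AAAAA", "TTTTT", "TTTTT"],
        {"p1": "P", "p2": "P", "q1": "Q", "q2": "Q"},
    )
    emit("two_fixed_demes", fixed, {"phi_st": 1.0})

    gapped = Alignment(
        ["g1", "g2", "g3"],
        ["AC-T", "ACNT", "ACGT"],
        {x: "G" for x in ("g1", "g2", "g3")},
    )
    emit("gapped_sites", gapped, {"analysed_sites_complete": 3})

    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(scenarios.MODELS))
    small_layout = {
        "MEX1": ("MEX", 8), "SAL1": ("SAL", 10), "PER1": ("PER", 7),
    }
    for model, child in zip(scenarios.MODELS, children):
        seed = int(child.generate_state(1)[0] % (2**31 - 1))
        aln, truth = generate_dataset(
            model, scenarios.default_priors(), seed, layout=small_layout
        )
        name = f"mid_{model.lower()}"
        emit(name, aln, {"truth": json.loads(truth.to_json())})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
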