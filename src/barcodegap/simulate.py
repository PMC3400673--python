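"""Synthetic barcode cohorts with known ground truth.

The generator emulates the statistical structure of a barcoded radiation: a
clock-like (ultrametric) hierarchy of clades, species within clades and
individuals within species, with sequences evolved along the tree under the
same two-parameter (K2P) substitution process the estimator assumes.  Branch
lengths are in expected substitutions per site, so simulated truth and K2P
estimates share units and parameter-recovery tests are direct.

Nested depths (all expected substitutions/site from the present):

* ``clade_depth``      — clades split at the root; between-clade pairwise
  divergence is ``2 * clade_depth``;
* ``species_depth``    — species split within their clade;
* ``intraspecies_depth`` — individuals coalesce within their species.

Defaults mirror the rainbowfish survey's observed levels: between-clade
pairwise divergence about 0.137, within-clade among-species about 0.059,
within-species about 0.0065.  Planted "new lineages" are isolated singleton
pendant branches attached at a clade's crown (their nearest neighbour is
about ``2 * species_depth`` away), and clades are mapped to geographic
regions so that regions are phylogenetically clustered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .dataio import (
    DEFAULT_REGIONS,
    BarcodeDataset,
    SequenceRecord,
    SpecimenMetadata,
    write_fasta,
    write_metadata,
)
from .njtree import PhyloTree

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

# vertebrate mitochondrial stop codons, as base-index triplets
_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_BASES = "ACGT"
_STOP_TRIPLES = {tuple(_BASES.index(b) for b in s) for s in _STOPS}

_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_clades: int = 4
    species_per_clade: int = 13
    individuals_per_species: int = 5
    seq_length: int = 650
    kappa: float = 4.0  # transition/transversion rate ratio
    clade_depth: float = 0.0685
    species_depth: float = 0.0295
    intraspecies_depth: float = 0.00325
    n_new_lineages: int = 15
    stop_free: bool = True
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_map: dict[str, tuple[str, ...]] | None = None
    #: optional dating scenario: rescale depths so the between-clade pairwise
    #: divergence equals true_rate * true_event_age
    true_rate: float | None = None
    true_event_age: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.intraspecies_depth < self.species_depth < self.clade_depth):
            raise ValueError(
                "depths must nest: 0 < intraspecies < species < clade"
            )
        if self.n_clades < 1 or self.species_per_clade < 1 or self.individuals_per_species < 1:
            raise ValueError("counts must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis should recover."""

    tree: PhyloTree  # rooted ultrametric truth
    lineage_of: dict[str, str]  # individual id -> species/lineage label
    clade_of: dict[str, str]  # lineage -> clade label
    region_of: dict[str, str]  # lineage -> region
    new_lineages: frozenset[str]
    config: SimulationConfig
    true_rate: float | None = None
    true_event_age: float | None = None

    def region_assignment(self) -> dict[str, str]:
        return dict(self.region_of)


def _resolved_config(cfg: SimulationConfig) -> SimulationConfig:
    if cfg.true_rate is None and cfg.true_event_age is None:
        return cfg
    if cfg.true_rate is None or cfg.true_event_age is None:
        raise ValueError("true_rate and true_event_age must be given together")
    target = cfg.true_rate * cfg.true_event_age / 2.0
    scale = target / cfg.clade_depth
    return replace(
        cfg,
        clade_depth=target,
        species_depth=cfg.species_depth * scale,
        intraspecies_depth=cfg.intraspecies_depth * scale,
    )


def simulate_tree(cfg: SimulationConfig) -> GroundTruth:
    """Build the ultrametric ground-truth tree and the lineage/region maps.

    Deterministic: the topology is fully determined by the config (the RNG
    only enters at sequence evolution).  New lineages are distributed
    round-robin over clades; regions are split round-robin over clades so
    each region hosts lineages of a single clade.
    """
    cfg = _resolved_config(cfg)
    cd, sd, ips = cfg.clade_depth, cfg.species_depth, cfg.intraspecies_depth
    clade_labels = [_ROMAN[i] if i < len(_ROMAN) else f"C{i + 1}" for i in range(cfg.n_clades)]

    if cfg.region_map is not None:
        region_map = cfg.region_map
    else:
        region_map = {
            c: tuple(cfg.regions[i :: cfg.n_clades]) or (cfg.regions[i % len(cfg.regions)],)
            for i, c in enumerate(clade_labels)
        }

    lineage_of: dict[str, str] = {}
    clade_of: dict[str, str] = {}
    region_of: dict[str, str] = {}
    new_lineages: list[str] = []

    new_per_clade = [
        cfg.n_new_lineages // cfg.n_clades
        + (1 if i < cfg.n_new_lineages % cfg.n_clades else 0)
        for i in range(cfg.n_clades)
    ]

    clade_parts = []
    for ci, clade in enumerate(clade_labels):
        parts = []
        lineages_in_clade = []
        for si in range(cfg.species_per_clade):
            sp = f"{clade}_s{si + 1:02d}"
            lineages_in_clade.append(sp)
            ids = [f"{sp}_i{k + 1}" for k in range(cfg.individuals_per_species)]
            for ind in ids:
                lineage_of[ind] = sp
            clade_of[sp] = clade
            if cfg.individuals_per_species == 1:
                parts.append(f"{ids[0]}:{sd:.12g}")
            else:
                tips = ",".join(f"{ind}:{ips:.12g}" for ind in ids)
                parts.append(f"({tips}):{sd - ips:.12g}")
        for ni in range(new_per_clade[ci]):
            nl = f"{clade}_n{ni + 1:02d}"
            ind = f"{nl}_i1"
            lineage_of[ind] = nl
            clade_of[nl] = clade
            new_lineages.append(nl)
            lineages_in_clade.append(nl)
            parts.append(f"{ind}:{sd:.12g}")
        for k, sp in enumerate(lineages_in_clade):
            region_of[sp] = region_map[clade][k % len(region_map[clade])]
        clade_parts.append(f"({','.join(parts)}):{cd - sd:.12g}")

    newick = f"({','.join(clade_parts)});"
    tree = PhyloTree.from_newick(newick, rooted=True)
    return GroundTruth(
        tree=tree,
        lineage_of=lineage_of,
        clade_of=clade_of,
        region_of=region_of,
        new_lineages=frozenset(new_lineages),
        config=cfg,
        true_rate=cfg.true_rate,
        true_event_age=cfg.true_event_age,
    )


def _k2p_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t.

    Rates are normalized so one unit of branch length is one expected
    substitution per site: alpha + 2*beta = 1 with alpha/beta = kappa.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _mutate(parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    p_same, p_ts, p_tv = _k2p_probs(t, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    m_ts = (u >= p_same) & (u < p_same + p_ts)
    m_tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    m_tv2 = u >= p_same + p_ts + p_tv
    child[m_ts] = _TS_PARTNER[parent[m_ts]]
    child[m_tv1] = _TV1[parent[m_tv1]]
    child[m_tv2] = _TV2[parent[m_tv2]]
    return child


def _stop_codon_starts(seq: np.ndarray) -> list[int]:
    return [
        k
        for k in range(0, seq.size - 2, 3)
        if (int(seq[k]), int(seq[k + 1]), int(seq[k + 2])) in _STOP_TRIPLES
    ]


def _mutate_stop_free(
    parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Mutate, rejecting codon draws that create an in-frame stop.

    Offending codons are redrawn (conditioned on the parent codon) up to a
    bounded number of attempts, then reverted to the parent codon — the
    parent is stop-free by induction from a stop-free root.
    """
    child = _mutate(parent, t, kappa, rng)
    for start in _stop_codon_starts(child):
        for _ in range(50):
            redo = _mutate(parent[start : start + 3], t, kappa, rng)
            if tuple(int(b) for b in redo) not in _STOP_TRIPLES:
                child[start : start + 3] = redo
                break
        else:
            child[start : start + 3] = parent[start : start + 3]
    return child


def _root_sequence(length: int, stop_free: bool, rng: np.random.Generator) -> np.ndarray:
    seq = rng.integers(0, 4, size=length)
    if stop_free:
        for start in _stop_codon_starts(seq):
            while (int(seq[start]), int(seq[start + 1]), int(seq[start + 2])) in _STOP_TRIPLES:
                seq[start : start + 3] = rng.integers(0, 4, size=3)
    return seq


def evolve_sequences(gt: GroundTruth, cfg: SimulationConfig | None = None) -> BarcodeDataset:
    """Evolve sequences down the ground-truth tree; return the joined dataset.

    Root sequence is uniform over bases (codon-rejected to be stop-free when
    ``stop_free``); each branch applies the K2P process with the configured
    transition/transversion ratio and expected substitutions equal to the
    branch length.
    """
    cfg = _resolved_config(cfg or gt.config)
    rng = np.random.default_rng(cfg.seed)
    mut = _mutate_stop_free if cfg.stop_free else _mutate
    root = gt.tree.tree
    seqs: dict[int, np.ndarray] = {id(root): _root_sequence(cfg.seq_length, cfg.stop_free, rng)}
    records: list[SequenceRecord] = []
    for node in root.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        child_seq = mut(parent_seq, node.length or 0.0, cfg.kappa, rng)
        seqs[id(node)] = child_seq
        if node.is_tip():
            records.append(
                SequenceRecord(id=node.name, seq="".join(_BASES[b] for b in child_seq))
            )

    meta = []
    for rec in records:
        sp = gt.lineage_of[rec.id]
        clade = gt.clade_of[sp]
        meta.append(
            SpecimenMetadata(
                id=rec.id,
                species=sp,
                genus=f"Genus{clade}",
                family="Simfamilia",
                order="Simorder",
                clade=clade,
                locality=f"Loc_{sp}",
                region=gt.region_of[sp],
            )
        )
    return BarcodeDataset(records=records, meta=meta, alignment_mode="prealigned")


def scenario_paper_like(seed: int = 0, **overrides) -> tuple[BarcodeDataset, GroundTruth]:
    """One call, full fixture: 4 clades x 13 species x 5 individuals plus 15
    planted singleton lineages over 7 phylogenetically clustered regions."""
    cfg = SimulationConfig(seed=seed, **overrides)
    gt = simulate_tree(cfg)
    ds = evolve_sequences(gt, cfg)
    return ds, gt


def scenario_random_regions(seed: int = 0, **overrides) -> tuple[BarcodeDataset, GroundTruth]:
    """Null variant: same cohort, but lineage-to-region assignment randomized
    (regions are NOT phylogenetically clustered); Pi_ST should sit near 0."""
    ds, gt = scenario_paper_like(seed=seed, **overrides)
    rng = np.random.default_rng(seed + 1)
    lineages = sorted(gt.region_of)
    shuffled = [gt.region_of[l] for l in lineages]
    rng.shuffle(shuffled)
    gt.region_of = dict(zip(lineages, shuffled))
    meta = [replace(m, region=gt.region_of[m.species]) for m in ds.meta]
    return BarcodeDataset(records=ds.records, meta=meta, alignment_mode=ds.alignment_mode), gt


def write_scenario(ds: BarcodeDataset, gt: GroundTruth, outdir: str | Path) -> None:
    """Emit the dataio formats plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, outdir / "sequences.fasta")
    write_metadata(ds.meta, outdir / "metadata.tsv")
    truth = {
        "tree_newick": gt.tree.to_newick(),
        "lineage_of": gt.lineage_of,
        "clade_of": gt.clade_of,
        "region_of": gt.region_of,
        "new_lineages": sorted(gt.new_lineages),
        "true_rate": gt.true_rate,
        "true_event_age": gt.true_event_age,
        "seed": gt.config.seed,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
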