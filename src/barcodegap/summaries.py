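"""Barcode-gap analytics.

Level-wise K2P summaries (the classic within-species / within-genus-among-
species / within-family / within-order ladder), nearest-neighbour distances
with the 0.1 / 1.0 / 2.7 % bins, and per-species diagnostics (exclusive
cluster on the NJ tree, haplotype sharing, candidate new lineages).

Distance summaries are printed on the percent scale except the SD, which is
reported on the proportion scale, mirroring the conventional table layout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import BarcodeDataset
from .k2p import DistanceMatrix
from .njtree import PhyloTree, is_exclusive

logger = logging.getLogger("barcodegap")

LEVELS = (
    "within_species",
    "within_genus_among_species",
    "within_family_among_genera",
    "within_order_among_families",
)

#: Nearest-neighbour distance bins, percent scale, half-open on the left:
#: [0, 0.1), [0.1, 1.0), [1.0, 2.7), [2.7, inf).
BIN_EDGES = (0.1, 1.0, 2.7)
BIN_LABELS = ("<0.1", "0.1-1.0", "1.0-2.7", ">2.7")


@dataclass(frozen=True)
class LevelSummary:
    level: str
    n_individuals: int
    n_taxa: int
    n_comparisons: int
    min: float  # percent
    mean: float  # percent
    max: float  # percent
    sd: float  # proportion scale, as conventionally printed


@dataclass(frozen=True)
class NeighborRecord:
    species: str
    nn_species: str
    nn_distance: float  # percent
    bin: str


@dataclass(frozen=True)
class SpeciesDiagnosis:
    species: str
    exclusive: bool
    shares_haplotype_with: frozenset[str]
    min_interspecific: float  # proportion
    max_intraspecific: float  # proportion, NaN for singletons
    status: str  # captured | mixed | new_lineage_candidate


def _pair_level_codes(ds: BarcodeDataset) -> np.ndarray:
    """Level index (0..3) for every unordered pair; -1 if no rank is shared."""
    mf = ds.meta_frame()
    levels = np.full((len(ds), len(ds)), -1, dtype=np.int8)
    for lvl, col in enumerate(("species", "genus", "family", "order")):
        codes = pd.factorize(mf[col])[0]
        same = codes[:, None] == codes[None, :]
        same &= (codes != -1)[:, None] & (codes != -1)[None, :]
        levels[same & (levels == -1)] = lvl
    return levels


def level_partition(m: DistanceMatrix, ds: BarcodeDataset) -> list[LevelSummary]:
    """Assign every pair to its finest shared taxonomic rank and summarize.

    Species with a single individual contribute no within-species pair;
    ``n_individuals``/``n_taxa`` count the individuals and the grouping taxa
    that appear in at least one comparison at the level.  Missing pairs are
    excluded from every level.
    """
    if m.ids != ds.ids:
        raise ValueError("distance matrix and dataset ids differ")
    mf = ds.meta_frame()
    level_codes = _pair_level_codes(ds)
    iu, ju = np.triu_indices(len(ds), k=1)
    dvals = m.d[iu, ju]
    lvls = level_codes[iu, ju]
    present = ~np.isnan(dvals)

    group_col = {0: "species", 1: "genus", 2: "family", 3: "order"}
    out = []
    for lvl, name in enumerate(LEVELS):
        mask = (lvls == lvl) & present
        dv = dvals[mask]
        idx = np.unique(np.concatenate([iu[mask], ju[mask]]))
        taxa = mf.iloc[idx][group_col[lvl]].nunique() if idx.size else 0
        if dv.size:
            out.append(LevelSummary(
                level=name,
                n_individuals=int(idx.size),
                n_taxa=int(taxa),
                n_comparisons=int(dv.size),
                min=float(dv.min() * 100),
                mean=float(dv.mean() * 100),
                max=float(dv.max() * 100),
                sd=float(dv.std(ddof=1)) if dv.size > 1 else 0.0,
            ))
        else:
            out.append(LevelSummary(name, 0, 0, 0, math.nan, math.nan, math.nan, math.nan))
    return out


def fold_ratio(rows: list[LevelSummary]) -> float:
    """Congeneric-over-conspecific mean divergence ratio.

    mean(within_genus_among_species) / mean(within_species).  Raises on a
    zero or undefined denominator.  Use :func:`render_fold` for the
    "N-fold" rendering.
    """
    by = {r.level: r for r in rows}
    num = by["within_genus_among_species"].mean
    den = by["within_species"].mean
    if not den or math.isnan(den):
        raise ZeroDivisionError("within-species mean divergence is zero or undefined")
    return num / den


def render_fold(ratio: float) -> str:
    return f"{round(ratio)}-fold"


def assign_bin(nn_percent: float) -> str:
    """Bin a nearest-neighbour distance (percent), half-open on the left."""
    for edge, label in zip(BIN_EDGES, BIN_LABELS):
        if nn_percent < edge:
            return label
    return BIN_LABELS[-1]


def species_min_distances(m: DistanceMatrix, ds: BarcodeDataset) -> pd.DataFrame:
    """Species x species matrix of minimum between-individual K2P distance."""
    mf = ds.meta_frame()
    species = sorted(mf["species"].unique())
    members = {s: np.flatnonzero((mf["species"] == s).to_numpy()) for s in species}
    k = len(species)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            block = m.d[np.ix_(members[species[i]], members[species[j]])]
            if np.isnan(block).all():
                continue
            out[i, j] = out[j, i] = np.nanmin(block)
    return pd.DataFrame(out, index=species, columns=species)


@dataclass
class NeighborReport:
    records: list[NeighborRecord]
    by_genus: pd.DataFrame  # genus x bin counts
    by_clade: pd.DataFrame  # clade x bin counts


def nearest_neighbors(m: DistanceMatrix, ds: BarcodeDataset) -> NeighborReport:
    """Nearest-neighbour distance per species, binned, tallied by genus/clade.

    nn_distance is the minimum over heterospecific individual pairs, percent
    scale.  Species without any comparable heterospecific pair are excluded
    with a warning.
    """
    mf = ds.meta_frame()
    smin = species_min_distances(m, ds)
    if len(smin) < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 species")
    sp_attr = mf.drop_duplicates("species").set_index("species")
    records = []
    for sp in smin.index:
        row = smin.loc[sp].drop(sp)
        if row.isna().all():
            logger.warning("species %r has no comparable heterospecific pairs; excluded", sp)
            continue
        nn = row.idxmin()
        pct = float(row.min() * 100)
        records.append(NeighborRecord(sp, nn, pct, assign_bin(pct)))

    def _tally(attr: str) -> pd.DataFrame:
        rows = {}
        for rec in records:
            key = sp_attr.loc[rec.species, attr]
            rows.setdefault(key, dict.fromkeys(BIN_LABELS, 0))
            rows[key][rec.bin] += 1
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(BIN_LABELS)).fillna(0)
        df.insert(0, "n_species", df.sum(axis=1).astype(int))
        return df.sort_index()

    return NeighborReport(records=records, by_genus=_tally("genus"), by_clade=_tally("clade"))


def diagnose_species(
    m: DistanceMatrix,
    t: PhyloTree,
    ds: BarcodeDataset,
    new_localities: set[str] | frozenset[str] = frozenset(),
) -> list[SpeciesDiagnosis]:
    """Per-species barcode diagnosis on the rooted NJ tree.

    A species is *captured* when its individuals form an exclusive cluster
    and its minimum interspecific distance is positive; *mixed* when either
    fails (haplotype sharing implies distance zero implies mixed); and a
    population named in *new_localities* whose cluster is exclusive and
    distinct is a *new_lineage_candidate* (a private barcode cluster).
    Species with no comparable heterospecific pair are excluded with a
    warning.
    """
    if not t.rooted:
        raise ValueError("diagnosis requires the midpoint-rooted tree")
    mf = ds.meta_frame()
    smin = species_min_distances(m, ds)
    out = []
    for sp in smin.index:
        ids = set(mf.index[mf["species"] == sp])
        hetero = smin.loc[sp].drop(sp)
        if hetero.isna().all():
            logger.warning("species %r has no heterospecific comparisons; excluded", sp)
            continue
        min_inter = float(hetero.min())
        sharing = frozenset(hetero.index[hetero == 0.0])
        exclusive = is_exclusive(t, ids)
        if len(ids) > 1:
            block = m.d[np.ix_(sorted(mf.index.get_indexer(list(ids))),
                               sorted(mf.index.get_indexer(list(ids))))]
            iu = np.triu_indices(len(ids), k=1)
            vals = block[iu]
            max_intra = float(np.nanmax(vals)) if not np.isnan(vals).all() else math.nan
        else:
            max_intra = math.nan
        if not exclusive or min_inter == 0.0:
            status = "mixed"
        elif sp in new_localities:
            status = "new_lineage_candidate"
        else:
            status = "captured"
        out.append(SpeciesDiagnosis(
            species=sp,
            exclusive=exclusive,
            shares_haplotype_with=sharing,
            min_interspecific=min_inter,
            max_intraspecific=max_intra,
            status=status,
        ))
    return out


def level_table(rows: list[LevelSummary]) -> pd.DataFrame:
    """Level summaries as a 4-row DataFrame (percent min/mean/max, proportion SD)."""
    return pd.DataFrame([vars(r) for r in rows]).set_index("level")


def diagnosis_table(diags: list[SpeciesDiagnosis]) -> pd.DataFrame:
    df = pd.DataFrame([
        {
            "species": d.species,
            "exclusive": d.exclusive,
            "shares_haplotype_with": ";".join(sorted(d.shares_haplotype_with)),
            "min_interspecific": d.min_interspecific,
            "max_intraspecific": d.max_intraspecific,
            "status": d.status,
        }
        for d in diags
    ])
    return df.set_index("species")
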