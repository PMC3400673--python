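"""Kimura 2-parameter distances.

The K2P model corrects the observed proportions of transitions (P: A<->G,
C<->T) and transversions (Q: every other mismatch) for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Distances are held as substitutions per site (proportion scale); reports that
mirror the published tables multiply by 100.  Pairs are compared under
pairwise deletion: any site where either sequence carries a gap or an IUPAC
ambiguity code is skipped, and a pair whose comparable-site count falls below
a configurable floor is recorded as missing rather than given a distance from
a tiny overlap (mixed 650/1800-bp products make this floor necessary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import BarcodeDataset, SequenceRecord

#: Minimum number of comparable sites for a pair to receive a distance.
DEFAULT_MIN_OVERLAP = 300


class SaturationError(ValueError):
    """Divergence too high for the K2P correction (a log argument <= 0)."""


class MissingPairError(ValueError):
    """No (or too few) comparable sites between two sequences."""


@dataclass(frozen=True)
class PairComparison:
    """Site classification for one sequence pair under pairwise deletion."""

    sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.sites:
            raise ValueError("more substitutions than compared sites")

    @property
    def P(self) -> float:
        """Transition proportion."""
        return self.transitions / self.sites if self.sites else math.nan

    @property
    def Q(self) -> float:
        """Transversion proportion."""
        return self.transversions / self.sites if self.sites else math.nan


# base encoding: A=0, C=1, G=2, T=3, anything else (ambiguity/gap) = 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_IS_PURINE = np.array([True, False, True, False, False])


def _encode(seq: str, length: int | None = None) -> np.ndarray:
    """Encode a sequence as uint8 codes, right-padded with 4 (gap) to *length*."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[arr]
    if length is not None and length > codes.size:
        codes = np.concatenate([codes, np.full(length - codes.size, 4, dtype=np.uint8)])
    return codes


def compare_pair(a: SequenceRecord, b: SequenceRecord) -> PairComparison:
    """Count comparable sites, transitions and transversions for one pair.

    Sequences of unequal length are compared over the aligned prefix (the
    shorter is right-padded with gaps).  Sites with a gap or ambiguity code in
    either sequence are skipped.
    """
    n = max(a.length, b.length)
    ca, cb = _encode(a.seq, n), _encode(b.seq, n)
    valid = (ca < 4) & (cb < 4)
    diff = valid & (ca != cb)
    ts = diff & (_IS_PURINE[ca] == _IS_PURINE[cb])
    return PairComparison(
        sites=int(valid.sum()),
        transitions=int(ts.sum()),
        transversions=int(diff.sum() - ts.sum()),
    )


def k2p_distance(c: PairComparison) -> float:
    """K2P distance (substitutions/site) from a pair comparison.

    Raises :class:`MissingPairError` when no sites were comparable and
    :class:`SaturationError` when the correction's log arguments are
    non-positive (divergence beyond what the model can correct).
    """
    if c.sites == 0:
        raise MissingPairError("zero comparable sites")
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated pair: P={c.P:.4f}, Q={c.Q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # normalize -0.0


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with per-pair compared-site counts.

    ``d`` holds substitutions/site; missing or saturated pairs are NaN with the
    reason in ``flags`` keyed by the (i, j) index pair (i < j).
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray
    flags: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_missing(self) -> int:
        return len(self.flags)

    @property
    def complete(self) -> bool:
        return not self.flags

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        scale = 100.0 if percent else 1.0
        return pd.DataFrame(self.d * scale, index=self.ids, columns=self.ids)

    def to_csv(self, path, percent: bool = False) -> None:
        """Square CSV with an id header row and column."""
        self.to_frame(percent=percent).to_csv(path, index_label="id", lineterminator="\n")

    def to_phylip(self, path) -> None:
        """PHYLIP square format (relaxed names)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in np.nan_to_num(self.d[i]))
                fh.write(f"{name}  {row}\n")


def encode_dataset(ds: BarcodeDataset) -> np.ndarray:
    """Encode all sequences into one (n, L) uint8 matrix, gap-padded."""
    L = max(r.length for r in ds.records)
    return np.vstack([_encode(r.seq, L) for r in ds.records])


def distance_matrix(
    ds: BarcodeDataset, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs K2P matrix under pairwise deletion.

    Pairs with fewer than *min_overlap* comparable sites are flagged
    ``short-overlap``; saturated pairs are flagged ``saturated``.  Both get
    NaN distances rather than misleading numbers.
    """
    codes = encode_dataset(ds)
    n = codes.shape[0]
    ok = codes < 4
    purine = _IS_PURINE[codes]
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=np.int64)
    flags: dict[tuple[int, int], str] = {}
    for i in range(n - 1):
        valid = ok[i] & ok[i + 1 :]  # (n-i-1, L)
        diff = valid & (codes[i] != codes[i + 1 :])
        ts = diff & (purine[i] == purine[i + 1 :])
        s = valid.sum(axis=1)
        nts = ts.sum(axis=1)
        ntv = diff.sum(axis=1) - nts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = nts / s
            Q = ntv / s
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            dist = -0.5 * np.log(w1) - 0.25 * np.log(w2) + 0.0  # avoid -0.0
        for k, j in enumerate(range(i + 1, n)):
            if s[k] < min_overlap:
                flags[(i, j)] = "short-overlap"
                d[i, j] = d[j, i] = np.nan
            elif w1[k] <= 0 or w2[k] <= 0:
                flags[(i, j)] = "saturated"
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = dist[k]
            sites[i, j] = sites[j, i] = s[k]
    return DistanceMatrix(ids=ds.ids, d=d, sites=sites, flags=flags)
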