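"""Phylogenetic community structure: the Pi_ST index and its permutation test.

Pi_ST is an additive-partitioning statistic over a lineage x site
presence/absence matrix and a phylogenetic distance matrix among lineages:

    Pi_ST = 1 - delta_within / delta_among

where delta_within is the mean distance between distinct lineages co-occurring
in a site (averaged over sites) and delta_among the mean distance between
distinct lineages drawn from two different sites (averaged over site pairs).
Pi_ST > 0 means sites are phylogenetically clustered (co-occurring lineages
are closer than expected), Pi_ST < 0 phylogenetic dispersion.

Significance comes from permuting lineage identities on the distance matrix;
the one-sided upper-tail p-value uses the standard +1 correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .k2p import DistanceMatrix

logger = logging.getLogger("barcodegap")


class UndefinedPiST(ValueError):
    """Pi_ST undefined: no co-occurring pairs, or delta_among is zero."""


@dataclass
class CommunityMatrix:
    """Lineage x site presence/absence.

    Sites hosting fewer than 2 lineages carry no within-site pair and are
    dropped with a warning; lineages absent everywhere are an error.
    """

    lineages: list[str]
    sites: list[str]
    presence: np.ndarray  # bool, (n_lineages, n_sites)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.lineages), len(self.sites)):
            raise ValueError("presence shape does not match labels")
        if (~self.presence.any(axis=1)).any():
            empty = [l for l, row in zip(self.lineages, self.presence) if not row.any()]
            raise ValueError(f"lineages present in no site: {empty}")
        keep = self.presence.sum(axis=0) >= 2
        if not keep.all():
            dropped = [s for s, k in zip(self.sites, keep) if not k]
            logger.warning("dropping sites with <2 lineages: %s", dropped)
            self.sites = [s for s, k in zip(self.sites, keep) if k]
            self.presence = self.presence[:, keep]
        if len(self.sites) < 2:
            raise ValueError("need at least 2 sites with >=2 lineages")

    @classmethod
    def from_assignments(cls, assignment: dict[str, str]) -> "CommunityMatrix":
        """Build from a lineage -> site mapping (each lineage in one site)."""
        lineages = sorted(assignment)
        sites = sorted(set(assignment.values()))
        presence = np.zeros((len(lineages), len(sites)), dtype=bool)
        for i, lin in enumerate(lineages):
            presence[i, sites.index(assignment[lin])] = True
        return cls(lineages=lineages, sites=sites, presence=presence)

    @classmethod
    def from_csv(cls, path) -> "CommunityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            lineages=[str(x) for x in df.index],
            sites=[str(c) for c in df.columns],
            presence=df.to_numpy(dtype=bool),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.presence.astype(int), index=self.lineages, columns=self.sites
        ).to_csv(path, index_label="lineage", lineterminator="\n")


@dataclass
class PiSTResult:
    pi_st: float
    delta_within: float
    delta_among: float
    n_permutations: int = 0
    p_value: float = float("nan")
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "pi_st": self.pi_st,
            "delta_within": self.delta_within,
            "delta_among": self.delta_among,
            "n_perm": self.n_permutations,
            "p_value": None if np.isnan(self.p_value) else self.p_value,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _deltas(presence: np.ndarray, D: np.ndarray) -> tuple[float, float]:
    """(delta_within, delta_among) from a boolean presence matrix and D.

    Within: per site, mean distance over unordered pairs of distinct
    co-occurring lineages, then averaged over sites.  Among: per unordered
    site pair, mean distance over cross-site lineage pairs excluding
    same-lineage pairs, then averaged over site pairs.
    """
    X = presence.astype(float).T  # (S, L)
    n = X.sum(axis=1)
    G = X @ D @ X.T  # ordered-pair distance sums between site pools
    overlap = X @ X.T  # shared lineage counts

    within_terms = []
    for s in range(X.shape[0]):
        pairs = n[s] * (n[s] - 1) / 2.0
        if pairs > 0:
            within_terms.append((G[s, s] / 2.0) / pairs)
    if not within_terms:
        raise UndefinedPiST("no site hosts two distinct lineages")
    delta_within = float(np.mean(within_terms))

    among_terms = []
    for s in range(X.shape[0]):
        for t in range(s + 1, X.shape[0]):
            pairs = n[s] * n[t] - overlap[s, t]  # exclude same-lineage pairs
            if pairs > 0:
                among_terms.append(G[s, t] / pairs)
    if not among_terms:
        raise UndefinedPiST("no cross-site pair of distinct lineages")
    delta_among = float(np.mean(among_terms))
    return delta_within, delta_among


def pi_st(cm: CommunityMatrix, pd_matrix: DistanceMatrix) -> PiSTResult:
    """Compute the Pi_ST index (no test).

    *pd_matrix* must cover every lineage of *cm*; extra lineages are ignored.
    Raises :class:`UndefinedPiST` when delta_among is zero or no co-occurring
    pairs exist.
    """
    missing = set(cm.lineages) - set(pd_matrix.ids)
    if missing:
        raise KeyError(f"distance matrix lacks lineages: {sorted(missing)}")
    idx = [pd_matrix.ids.index(l) for l in cm.lineages]
    D = pd_matrix.d[np.ix_(idx, idx)]
    if np.isnan(D).any():
        raise ValueError("distance matrix has missing entries among community lineages")
    dw, da = _deltas(cm.presence, D)
    if da == 0.0:
        raise UndefinedPiST("delta_among is zero")
    return PiSTResult(pi_st=1.0 - dw / da, delta_within=dw, delta_among=da)


def pi_st_test(
    cm: CommunityMatrix,
    pd_matrix: DistanceMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PiSTResult:
    """Pi_ST with a one-sided (clustering) permutation p-value.

    The null shuffles lineage identities on the distance matrix (joint row
    and column permutation), leaving the presence pattern fixed;
    p = (1 + #{Pi_perm >= Pi_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = pi_st(cm, pd_matrix)
    idx = [pd_matrix.ids.index(l) for l in cm.lineages]
    D = pd_matrix.d[np.ix_(idx, idx)]
    rng = np.random.default_rng(seed)
    k = len(cm.lineages)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(k)
        dw, da = _deltas(cm.presence, D[np.ix_(p, p)])
        if da == 0.0:
            continue  # degenerate permutation; counts as non-exceeding
        if 1.0 - dw / da >= obs.pi_st - 1e-12:
            hits += 1
    return PiSTResult(
        pi_st=obs.pi_st,
        delta_within=obs.delta_within,
        delta_among=obs.delta_among,
        n_permutations=n_perm,
        p_value=(1 + hits) / (1 + n_perm),
        seed=seed,
    )
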