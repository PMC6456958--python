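"""Indicator species analysis (Dufrene-Legendre IndVal).

For each OTU and plant species, IndVal is the product of specificity -- the
OTU's mean relative abundance in the group divided by the sum of its group
means (group-equalized, so unequal sample sizes do not bias it) -- and
fidelity, the fraction of the group's samples containing the OTU.  Each OTU
is assigned the group maximizing its IndVal; significance comes from an
add-one permutation test of that maximum under group-label shuffling.  An
OTU is a strong indicator when IndVal > 0.6 and P < 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu_matrix import CountMatrix


def _relative_abundance(mat: CountMatrix) -> np.ndarray:
    x = mat.data.to_numpy(dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    return np.where(totals > 0, x / np.where(totals > 0, totals, 1), 0.0)


def _indval_matrix(rel: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """IndVal for every (group, OTU): specificity x fidelity, each in [0, 1]."""
    means = np.zeros((k, rel.shape[1]))
    fidelity = np.zeros((k, rel.shape[1]))
    for g in range(k):
        members = rel[codes == g]
        means[g] = members.mean(axis=0)
        fidelity[g] = (members > 0).mean(axis=0)
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        specificity = np.where(denom > 0, means / np.where(denom > 0, denom, 1), 0.0)
    return specificity * fidelity


def indval(mat: CountMatrix, groups: pd.Series | None = None) -> pd.DataFrame:
    """IndVal of every OTU for every plant species (group x OTU table).

    ``groups`` defaults to the metadata's plant_species labels.  Consumes
    relative abundances, so per-sample depth rescaling does not change it.
    All-zero OTUs score 0 for every group.
    """
    labels = (mat.metadata["plant_species"] if groups is None
              else groups.loc[mat.data.index])
    names = list(dict.fromkeys(labels))
    if len(names) < 2:
        raise ValueError("indicator analysis needs >= 2 groups")
    codes = np.array([names.index(g) for g in labels])
    iv = _indval_matrix(_relative_abundance(mat), codes, len(names))
    return pd.DataFrame(iv, index=names, columns=mat.data.columns)


@dataclass
class IndicatorResult:
    """Per-OTU best group, IndVal, permutation P and the strong-indicator flag."""

    table: pd.DataFrame  # columns: otu, group, indval, p, strong
    n_perm: int
    seed: int
    indval_threshold: float = 0.6
    alpha: float = 0.05

    def strong_indicators(self) -> pd.DataFrame:
        return self.table[self.table["strong"]]

    def summary(self) -> str:
        strong = self.strong_indicators()
        lines = [
            "Indicator species analysis",
            f"  OTUs tested        : {len(self.table)}",
            f"  permutations       : {self.n_perm} (seed {self.seed})",
            f"  strong indicators  : {len(strong)} "
            f"(IndVal > {self.indval_threshold}, P < {self.alpha})",
        ]
        if len(strong):
            per_group = strong.groupby("group").size()
            for g, n in per_group.items():
                lines.append(f"    {g}: {n}")
        return "\n".join(lines)


def indval_test(mat: CountMatrix, n_perm: int = 1000, seed: int = 0,
                groups: pd.Series | None = None,
                indval_threshold: float = 0.6,
                alpha: float = 0.05) -> IndicatorResult:
    """IndVal with an add-one permutation P for each OTU's maximum.

    Group labels are shuffled across samples ``n_perm`` times; the P value of
    an OTU is the add-one fraction of replicates whose maximum IndVal reaches
    the observed one, so P >= 1/(n_perm + 1).
    """
    labels = (mat.metadata["plant_species"] if groups is None
              else groups.loc[mat.data.index])
    names = list(dict.fromkeys(labels))
    if len(names) < 2:
        raise ValueError("indicator analysis needs >= 2 groups")
    codes = np.array([names.index(g) for g in labels])
    rel = _relative_abundance(mat)
    k = len(names)
    obs = _indval_matrix(rel, codes, k)
    best_group = obs.argmax(axis=0)
    obs_max = obs.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(rel.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        exceed += _indval_matrix(rel, perm, k).max(axis=0) >= obs_max - 1e-12
    p = (exceed + 1) / (n_perm + 1)

    table = pd.DataFrame({
        "otu": mat.data.columns,
        "group": [names[g] for g in best_group],
        "indval": obs_max,
        "p": p,
    })
    table["strong"] = (table["indval"] > indval_threshold) & (table["p"] < alpha)
    return IndicatorResult(table=table, n_perm=n_perm, seed=seed,
                           indval_threshold=indval_threshold, alpha=alpha)


class IndicatorSpeciesModel:
    """Model facade: IndicatorSpeciesModel(counts).fit(n_perm, seed)."""

    def __init__(self, counts: CountMatrix, groups: pd.Series | None = None):
        self.counts = counts
        self.groups = groups

    def fit(self, n_perm: int = 1000, seed: int = 0, **kwargs) -> IndicatorResult:
        return indval_test(self.counts, n_perm=n_perm, seed=seed,
                           groups=self.groups, **kwargs)
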