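"""Host/fungus preference statistics.

Two complementary views of host preference are computed from the
plant-species x OTU species-level matrix and its label-shuffling null
ensemble:

* the interaction specialization index d' of each OTU (and of each plant),
  a Kullback-Leibler divergence of the focal species' interaction
  frequencies from partner availability, rescaled between its minimum and
  maximum achievable values given the marginal totals -- 0 means purely
  opportunistic use of partners, 1 a perfect specialist.  The raw d' is
  standardized against the null ensemble:
  standardized d' = (d'_obs - mean d'_null) / sd d'_null.

* the two-dimensional preference 2DP(i, j) of every plant/OTU pair:
  (N_obs(i, j) - mean N_null(i, j)) / sd N_null(i, j), where N is the number
  of samples in which the pair co-occurred.  Cells whose null SD is zero are
  flagged undefined (reported as missing, never as a number).  Permutation
  P values use the add-one convention (the observed matrix counted among the
  replicates), two-tailed by default, and are FDR-adjusted across cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .null_models import NullEnsemble, shuffle_labels_ensemble
from .otu_matrix import BinaryMatrix, CountMatrix, SpeciesMatrix, to_species_matrix

TAILS = ("two", "greater", "less")


# ---------------------------------------------------------------------------
# d' -- Kullback-Leibler interaction specialization
# ---------------------------------------------------------------------------

def _kl(alloc: np.ndarray, total: float, q: np.ndarray) -> float:
    """KL divergence of alloc/total from availability q, over nonzero cells."""
    p = alloc[alloc > 0] / total
    return float(np.sum(p * np.log(p / q[alloc > 0])))


def _dmin(total: int, q: np.ndarray) -> float:
    """Minimum achievable KL term for an integer budget spread over partners.

    Greedy integer allocation proportional to availability: start from
    floor(total * q) and place each remaining unit on the cell that minimizes
    the resulting divergence (ties broken by lowest index).  Adding one unit
    to cell c changes only that cell's KL term, so the greedy step compares
    per-cell increments rather than recomputing the full divergence.
    """
    total = int(total)
    alloc = np.floor(total * q)
    rem = int(round(total - alloc.sum()))
    if rem > 0:
        ok = q > 0

        def term(a):
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (a / total) * np.log(a / (total * q))
            return np.where(ok & (a > 0), t, np.where(ok, 0.0, np.inf))

        with np.errstate(all="ignore"):
            delta = np.where(ok, term(alloc + 1) - term(alloc), np.inf)
        for _ in range(rem):
            c = int(np.argmin(delta))
            alloc[c] += 1
            # only cell c's increment changed
            with np.errstate(divide="ignore"):
                up = ((alloc[c] + 1) / total) * np.log((alloc[c] + 1) / (total * q[c]))
                cur = (alloc[c] / total) * np.log(alloc[c] / (total * q[c])) \
                    if alloc[c] > 0 else 0.0
            delta[c] = up - cur
    return _kl(alloc, total, q)


def _dprime_from_vectors(x: np.ndarray, availability: np.ndarray) -> float:
    """d' of one focal species: interaction vector x against partner totals."""
    total = float(x.sum())
    a_tot = float(availability.sum())
    if total <= 0:
        return float("nan")
    q = availability / a_tot
    d_obs = _kl(x.astype(float), total, q)
    d_max = np.log(a_tot / total)
    d_min = _dmin(int(round(total)), q)
    if d_max - d_min <= 1e-12:
        return 0.0
    return float(np.clip((d_obs - d_min) / (d_max - d_min), 0.0, 1.0))


def _dprime_matrix(mat: np.ndarray, axis: str) -> np.ndarray:
    """d' for every OTU (axis='otu') or every plant (axis='plant') of a matrix.

    Vectorized over focal species: the observed KL and the analytic maximum
    come from whole-matrix operations, and the greedy minimum is memoized per
    distinct focal total (it depends only on the total and the shared
    availability vector).
    """
    a = np.asarray(mat, dtype=float)
    if axis == "otu":
        a = a.T  # focal species as rows
    elif axis != "plant":
        raise ValueError(f"axis must be 'otu' or 'plant', got {axis!r}")
    totals = a.sum(axis=1)
    avail = a.sum(axis=0)
    a_tot = avail.sum()
    q = avail / a_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        p = a / totals[:, None]
        terms = np.where(a > 0, p * np.log(p / q[None, :]), 0.0)
        d_obs = terms.sum(axis=1)
        d_max = np.log(a_tot / totals)
    dmin_cache: dict[int, float] = {}
    out = np.full(len(totals), np.nan)
    for i, tot in enumerate(totals):
        if tot <= 0:
            continue
        key = int(round(tot))
        if key not in dmin_cache:
            dmin_cache[key] = _dmin(key, q)
        d_min = dmin_cache[key]
        if d_max[i] - d_min <= 1e-12:
            out[i] = 0.0
        else:
            out[i] = np.clip((d_obs[i] - d_min) / (d_max[i] - d_min), 0.0, 1.0)
    return out


def dprime(spm: SpeciesMatrix, axis: str, index) -> float:
    """Interaction specialization d' in [0, 1] of one focal OTU or plant.

    ``index`` is the OTU id (axis='otu') or plant species (axis='plant').
    A zero-total focal species is undefined and returned as NaN.
    """
    a = spm.data.to_numpy(dtype=float)
    if axis == "otu":
        j = spm.otus.index(index)
        return _dprime_from_vectors(a[:, j], a.sum(axis=1))
    if axis == "plant":
        i = spm.species.index(index)
        return _dprime_from_vectors(a[i, :], a.sum(axis=0))
    raise ValueError(f"axis must be 'otu' or 'plant', got {axis!r}")


def standardized_dprime(spm: SpeciesMatrix, ens: NullEnsemble, axis: str,
                        index) -> float:
    """(d'_observed - mean d'_null) / sd d'_null for one focal species.

    NaN when the null SD is zero (undefined, flagged rather than infinite).
    """
    series = standardized_dprime_all(spm, ens, axis)
    return float(series.loc[index])


def standardized_dprime_all(spm: SpeciesMatrix, ens: NullEnsemble,
                            axis: str) -> pd.Series:
    """Standardized d' for every OTU or plant at once (vectorized over replicates)."""
    _check_provenance(spm, ens)
    obs = _dprime_matrix(spm.data.to_numpy(), axis)
    null = np.stack([_dprime_matrix(ens.matrices[p], axis)
                     for p in range(ens.n_perm)])
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(null, axis=0)
        sd = np.nanstd(null, axis=0, ddof=1)
    out = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), np.nan)
    labels = spm.otus if axis == "otu" else spm.species
    return pd.Series(out, index=labels, name=f"std_dprime_{axis}")


# ---------------------------------------------------------------------------
# 2DP -- two-dimensional preference
# ---------------------------------------------------------------------------

@dataclass
class PreferenceResult:
    """Standardized d' per OTU/plant plus the 2DP matrix with P values."""

    std_dprime_otus: pd.Series
    std_dprime_plants: pd.Series
    twodp: pd.DataFrame          # NaN where undefined
    undefined: pd.DataFrame      # True exactly where null SD == 0
    p_raw: pd.DataFrame
    p_fdr: pd.DataFrame
    n_observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    n_perm: int = 0
    tails: str = "two"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (plant, OTU) pair."""
        rows = []
        for plant in self.twodp.index:
            for otu in self.twodp.columns:
                rows.append({
                    "plant": plant, "otu": otu,
                    "n_observed": int(self.n_observed.at[plant, otu]),
                    "null_mean": self.null_mean.at[plant, otu],
                    "null_sd": self.null_sd.at[plant, otu],
                    "twodp": self.twodp.at[plant, otu],
                    "p_raw": self.p_raw.at[plant, otu],
                    "p_fdr": self.p_fdr.at[plant, otu],
                    "defined": not self.undefined.at[plant, otu],
                })
        return pd.DataFrame(rows)


def _check_provenance(spm: SpeciesMatrix, ens: NullEnsemble) -> None:
    if spm.source_hash and ens.source_hash and spm.source_hash != ens.source_hash:
        raise ValueError(
            "null ensemble was generated from a different sample-level matrix "
            "than the observed species matrix"
        )
    if list(spm.otus) != list(ens.otus) or list(spm.species) != list(ens.species):
        raise ValueError("species/OTU labels differ between matrix and ensemble")


def two_dimensional_preference(spm: SpeciesMatrix, ens: NullEnsemble,
                               tails: str = "two") -> PreferenceResult:
    """2DP matrix with permutation P values, plus standardized d' vectors.

    2DP(i,j) = (N_obs - mean N_null) / sd N_null; a cell with null SD = 0 is
    undefined (NaN + flag).  P values use the add-one permutation convention,
    two-tailed by default: P = min(1, 2 min(Pr(N_null >= N_obs), Pr(N_null <=
    N_obs))) with the observed matrix counted in both tails.
    """
    if tails not in TAILS:
        raise ValueError(f"tails must be one of {TAILS}")
    _check_provenance(spm, ens)
    n_obs = spm.data.to_numpy(dtype=float)
    null = ens.matrices.astype(float)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(invalid="ignore"):
        twodp = np.where(undefined, np.nan, (n_obs - mean) / np.where(undefined, 1, sd))

    n = ens.n_perm
    ge = ((null >= n_obs).sum(axis=0) + 1) / (n + 1)
    le = ((null <= n_obs).sum(axis=0) + 1) / (n + 1)
    if tails == "two":
        p = np.minimum(1.0, 2.0 * np.minimum(ge, le))
    elif tails == "greater":
        p = np.minimum(1.0, ge)
    else:
        p = np.minimum(1.0, le)
    p_fdr = fdr_adjust(p.ravel()).reshape(p.shape)

    idx, cols = spm.data.index, spm.data.columns
    wrap = lambda a: pd.DataFrame(a, index=idx, columns=cols)
    return PreferenceResult(
        std_dprime_otus=standardized_dprime_all(spm, ens, "otu"),
        std_dprime_plants=standardized_dprime_all(spm, ens, "plant"),
        twodp=wrap(twodp),
        undefined=wrap(undefined),
        p_raw=wrap(p),
        p_fdr=wrap(p_fdr),
        n_observed=spm.data.copy(),
        null_mean=wrap(mean),
        null_sd=wrap(sd),
        n_perm=n,
        tails=tails,
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, capped at 1)."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def abundant_otu_mask(mat: CountMatrix, min_reads: int = 1000) -> list:
    """OTUs with total reads strictly greater than ``min_reads``.

    Used only to select which rows of the preference report are shown --
    preferences of rare OTUs are poorly estimable -- never to restrict the
    computation itself.
    """
    totals = mat.data.sum(axis=0)
    return list(totals.index[totals > min_reads])


def strong_preference_threshold(result: PreferenceResult,
                                alpha: float = 0.05) -> float:
    """Smallest |2DP| among cells significant after FDR (dataset-derived).

    This is the dataset's own boundary between 'strong' and ordinary
    preference/avoidance; NaN when nothing is significant.
    """
    mask = (result.p_fdr.to_numpy() < alpha) & ~result.undefined.to_numpy()
    vals = np.abs(result.twodp.to_numpy()[mask])
    return float(vals.min()) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

@dataclass
class HostPreferenceResults:
    """Fitted host-preference analysis with a text summary."""

    result: PreferenceResult
    abundant_otus: list = field(default_factory=list)
    n_perm: int = 0
    seed: int = 0

    def summary(self) -> str:
        r = self.result
        sig = (r.p_fdr.to_numpy() < 0.05) & ~r.undefined.to_numpy()
        thr = strong_preference_threshold(r)
        lines = [
            "Host/fungus preference analysis",
            f"  plants x OTUs          : {r.twodp.shape[0]} x {r.twodp.shape[1]}",
            f"  permutations           : {self.n_perm} (seed {self.seed}, {r.tails}-tailed)",
            f"  undefined 2DP cells    : {int(r.undefined.to_numpy().sum())}",
            f"  pairs with P_FDR<0.05  : {int(sig.sum())}",
            f"  strong |2DP| threshold : {thr:.3g}",
            f"  abundant OTUs reported : {len(self.abundant_otus)}",
        ]
        return "\n".join(lines)


class HostPreferenceModel:
    """Host-preference analysis of a sample-level presence/absence matrix.

    Parameters
    ----------
    data : BinaryMatrix or CountMatrix
        Sample x OTU matrix with plant-species metadata; counts are binarized.
    """

    def __init__(self, data: BinaryMatrix | CountMatrix):
        from .otu_matrix import binarize
        self.binary = data if isinstance(data, BinaryMatrix) else binarize(data)
        self.counts = data if isinstance(data, CountMatrix) else None

    def fit(self, n_perm: int = 1000, seed: int = 0, tails: str = "two",
            abundant_min_reads: int = 1000) -> HostPreferenceResults:
        spm = to_species_matrix(self.binary)
        ens = shuffle_labels_ensemble(self.binary, n_perm=n_perm, seed=seed)
        result = two_dimensional_preference(spm, ens, tails=tails)
        abundant = (abundant_otu_mask(self.counts, abundant_min_reads)
                    if self.counts is not None else [])
        return HostPreferenceResults(result=result, abundant_otus=abundant,
                                     n_perm=n_perm, seed=seed)
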