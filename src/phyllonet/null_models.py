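"""Permutation null models for the species-level matrix.

The single randomization used throughout the pipeline shuffles the plant
species labels across samples (sample rows of the binary matrix untouched)
and rebuilds the species-level matrix, so per-species sample counts and
per-OTU total occurrence are conserved exactly.  The ensemble of randomized
matrices feeds both the host-preference statistics (standardized d', 2DP) and
the randomization tests of the network architecture indices.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .otu_matrix import BinaryMatrix, SpeciesMatrix

SCHEMES = ("shuffle-labels",)


@dataclass
class NullEnsemble:
    """Ordered stack of randomized species-level matrices.

    ``matrices`` has shape (n_perm, n_species, n_otus); row/column labels and
    ``row_capacity`` are shared with the observed matrix.  ``source_hash``
    identifies the sample-level binary matrix the ensemble was generated from.
    """

    matrices: np.ndarray
    species: list
    otus: list
    row_capacity: pd.Series
    n_perm: int
    seed: int
    scheme: str = "shuffle-labels"
    source_hash: str = ""

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown null scheme: {self.scheme!r}")
        if self.matrices.shape != (self.n_perm, len(self.species), len(self.otus)):
            raise ValueError("ensemble array shape inconsistent with labels")

    def replicate(self, i: int) -> SpeciesMatrix:
        return SpeciesMatrix(
            pd.DataFrame(self.matrices[i], index=self.species, columns=self.otus),
            row_capacity=self.row_capacity,
            source_hash=self.source_hash,
        )


def shuffle_labels_ensemble(bin_mat: BinaryMatrix, n_perm: int, seed: int,
                            metadata: pd.DataFrame | None = None) -> NullEnsemble:
    """Build the label-shuffling null ensemble from a sample-level binary matrix.

    Each replicate permutes the plant-species labels uniformly at random over
    samples and recollapses to the species level.  Requires at least two
    distinct species (otherwise there is nothing to shuffle).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = bin_mat.metadata if metadata is None else metadata.loc[bin_mat.data.index]
    labels = meta["plant_species"]
    species = list(dict.fromkeys(labels))
    if len(species) < 2:
        raise ValueError("label shuffling needs >= 2 distinct plant species")
    codes = np.array([species.index(s) for s in labels])
    B = bin_mat.data.to_numpy()
    k = len(species)
    rng = np.random.default_rng(seed)
    out = np.empty((n_perm, k, B.shape[1]), dtype=np.int64)
    eye = np.eye(k, dtype=np.int64)
    for p in range(n_perm):
        perm = rng.permutation(codes)
        out[p] = eye[perm].T @ B
    capacity = pd.Series(np.bincount(codes, minlength=k), index=species)
    return NullEnsemble(
        matrices=out,
        species=species,
        otus=list(bin_mat.data.columns),
        row_capacity=capacity,
        n_perm=n_perm,
        seed=seed,
        source_hash=bin_mat.source_hash,
    )


def ensemble_stats(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of a collection of replicate values.

    A single value yields (value, nan): the SD is undefined, flagged as NaN
    rather than raising.  A constant collection yields SD exactly 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty collection")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return mean, sd
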