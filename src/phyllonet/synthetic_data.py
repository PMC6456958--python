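"""Study-shaped synthetic communities with controllable host specificity.

The generator emulates the processed design of a two-compartment leaf
mycobiome survey: 6 plant species x 8 replicate samples per compartment, a
few hundred OTUs, every sample normalized to a common read depth, long-tailed
(lognormal) OTU abundances, and a tunable mix of host generalists and
specialists.  A single specificity parameter theta interpolates each
specialist OTU's expected host distribution between uniform (theta = 0,
labels exchangeable) and fully host-specific (theta = 1):

    w(host) = (1 - theta) / n_hosts + theta * [host == focal host]

Per sample, an OTU survives an independent dropout draw (occupancy noise) and
the read vector is a single multinomial draw of the configured depth over the
surviving OTUs' expected mixture, so per-sample depth is conserved exactly.

:func:`generate_compartment_pair` produces an epiphyte-like and an
endophyte-like table over a partially shared OTU pool with stronger host
filtering inside the leaf (theta_endo > theta_epi), the contrast the
downstream network comparison is expected to recover.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import network_metrics as nm
from .otu_matrix import CountMatrix


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study design."""

    n_plant_species: int = 6
    samples_per_species: int = 8
    n_otus: int = 300
    depth: int = 6827
    specificity: float = 0.5          # theta in [0, 1]
    fraction_specialists: float = 0.8
    abundance_sigma: float = 2.5      # lognormal shape of base abundances
    occupancy_noise: float = 0.2      # per-sample, per-OTU dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.specificity <= 1:
            raise ValueError("specificity must lie in [0, 1]")
        if not 0 <= self.fraction_specialists <= 1:
            raise ValueError("fraction_specialists must lie in [0, 1]")
        if not 0 <= self.occupancy_noise < 1:
            raise ValueError("occupancy_noise must lie in [0, 1)")
        if min(self.n_plant_species, self.samples_per_species, self.n_otus) < 1:
            raise ValueError("design dimensions must be >= 1")


def generate_community(cfg: SimConfig, compartment: str = "epiphyte",
                       otu_ids: list | None = None,
                       sample_prefix: str | None = None) -> CountMatrix:
    """Draw one compartment's count table (samples x OTUs) plus metadata.

    Deterministic given ``cfg.seed``; ``otu_ids`` may impose a caller-defined
    OTU namespace (used for partially shared pools across compartments).
    """
    rng = np.random.default_rng(cfg.seed)
    h, reps, n_otus = cfg.n_plant_species, cfg.samples_per_species, cfg.n_otus
    hosts = [f"plant_{i + 1}" for i in range(h)]
    if otu_ids is None:
        otu_ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    elif len(otu_ids) != n_otus:
        raise ValueError("otu_ids length must equal n_otus")

    base = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n_otus)
    n_spec = int(round(cfg.fraction_specialists * n_otus))
    is_specialist = np.zeros(n_otus, dtype=bool)
    is_specialist[rng.choice(n_otus, size=n_spec, replace=False)] = True
    focal = rng.integers(0, h, size=n_otus)

    # host weight profile per OTU: uniform for generalists, theta-mixture for
    # specialists; every column sums to 1
    weights = np.full((h, n_otus), 1.0 / h)
    theta = cfg.specificity
    spec_cols = np.nonzero(is_specialist)[0]
    weights[:, spec_cols] = (1.0 - theta) / h
    weights[focal[spec_cols], spec_cols] += theta

    prefix = sample_prefix or compartment[:3]
    rows, sample_ids, meta_rows = [], [], []
    for hi, host in enumerate(hosts):
        for rep in range(reps):
            expected = base * weights[hi]
            if cfg.occupancy_noise > 0:
                keep = rng.random(n_otus) >= cfg.occupancy_noise
                expected = expected * keep
            if expected.sum() == 0:
                expected = base * weights[hi]  # degenerate dropout draw
            counts = rng.multinomial(cfg.depth, expected / expected.sum())
            rows.append(counts)
            sid = f"{prefix}_{host}_r{rep + 1}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "plant_species": host,
                              "compartment": compartment})
    data = pd.DataFrame(np.asarray(rows), index=sample_ids, columns=otu_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(data, meta)


def generate_compartment_pair(cfg_epi: SimConfig | None = None,
                              cfg_endo: SimConfig | None = None,
                              shared_fraction: float = 0.4
                              ) -> tuple[CountMatrix, CountMatrix]:
    """Epiphyte-like and endophyte-like tables over a partially shared pool.

    Defaults: theta_epi = 0.3, theta_endo = 0.8 (stronger host filtering in
    the leaf interior), with ``shared_fraction`` of the smaller OTU pool
    carrying the same OTU ids in both compartments.
    """
    if not 0 <= shared_fraction <= 1:
        raise ValueError("shared_fraction must lie in [0, 1]")
    cfg_epi = cfg_epi or SimConfig(specificity=0.3, seed=11)
    cfg_endo = cfg_endo or SimConfig(specificity=0.8, seed=12)
    n_shared = int(round(shared_fraction * min(cfg_epi.n_otus, cfg_endo.n_otus)))
    shared = [f"OTU_sh{i + 1:04d}" for i in range(n_shared)]
    epi_ids = shared + [f"OTU_ep{i + 1:04d}"
                        for i in range(cfg_epi.n_otus - n_shared)]
    endo_ids = shared + [f"OTU_en{i + 1:04d}"
                         for i in range(cfg_endo.n_otus - n_shared)]
    epi = generate_community(cfg_epi, compartment="epiphyte", otu_ids=epi_ids)
    endo = generate_community(cfg_endo, compartment="endophyte", otu_ids=endo_ids)
    return epi, endo


# ---------------------------------------------------------------------------
# analytic metric fixtures
# ---------------------------------------------------------------------------

def fixture_nested(n: int) -> nm.BipartiteNetwork:
    """Strictly nested staircase (pairwise distinct totals): WNODF = 100."""
    w = np.maximum(0, n - np.add.outer(np.arange(n), np.arange(n)))
    return nm.BipartiteNetwork(pd.DataFrame(
        w.astype(float),
        index=[f"plant_{i + 1}" for i in range(n)],
        columns=[f"OTU{j + 1}" for j in range(n)]))


def fixture_modular(k_modules: int, block: int) -> nm.BipartiteNetwork:
    """k equal disconnected complete blocks: Q_B = 1 - 1/k."""
    size = k_modules * block
    w = np.zeros((size, size))
    for b in range(k_modules):
        sl = slice(b * block, (b + 1) * block)
        w[sl, sl] = 1.0
    return nm.BipartiteNetwork(pd.DataFrame(
        w, index=[f"plant_{i + 1}" for i in range(size)],
        columns=[f"OTU{j + 1}" for j in range(size)]))


def fixture_checkerboard(n: int) -> nm.BipartiteNetwork:
    """Two rows with disjoint n-OTU supports: C-score = n^2, WNODF = 0."""
    w = np.zeros((2, 2 * n))
    w[0, :n] = 1.0
    w[1, n:] = 1.0
    return nm.BipartiteNetwork(pd.DataFrame(
        w, index=["plant_1", "plant_2"],
        columns=[f"OTU{j + 1}" for j in range(2 * n)]))
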