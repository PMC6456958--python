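"""Randomization tests, Z-scores, and cross-network comparison.

Each architecture index is computed on the observed species-level matrix and
on every replicate of its label-shuffling null ensemble.  A one-sample t test
of the replicate values against the observed value (the only reading
consistent with one observed network per compartment) gives the significance
of the departure, and Z = (observed - null mean) / null SD puts indices from
networks of different size and fill on a common scale so the epiphytic and
endophytic networks can be compared index by index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import network_metrics as nm
from .null_models import NullEnsemble, shuffle_labels_ensemble
from .otu_matrix import BinaryMatrix, to_species_matrix

DEFAULT_METRICS = ("weighted_connectance", "H2prime", "WNODF",
                   "modularity_QB", "cscore_rows", "cscore_cols")

# how to read the sign of a Z difference, per index
_VERDICTS = {
    "H2prime": ("more specialized", "less specialized"),
    "modularity_QB": ("more modular", "less modular"),
    "weighted_connectance": ("more connected", "less connected"),
    "WNODF": ("more nested", "more anti-nested"),
    "cscore_rows": ("more competitive (plants)", "less competitive (plants)"),
    "cscore_cols": ("more competitive (fungi)", "less competitive (fungi)"),
}


@dataclass
class RandomizationTest:
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    null_se: float
    t: float
    p: float
    p_perm: float
    z: float
    n_perm: int


def zscore(observed: float, null_mean: float, null_sd: float) -> float:
    """(observed - null mean) / null SD; NaN when the null SD is zero."""
    if null_sd < 0:
        raise ValueError("null SD must be non-negative")
    if null_sd == 0:
        return float("nan")
    return (observed - null_mean) / null_sd


def randomization_test(net: nm.BipartiteNetwork, metric: str,
                       ens: NullEnsemble, seed: int = 0,
                       max_undefined_frac: float = 0.01,
                       **metric_kwargs) -> RandomizationTest:
    """Observed-vs-null test of one index against a permutation ensemble.

    The index is evaluated on the observed matrix and every replicate with
    identical settings (including the modularity optimizer, so optimization
    quality cancels in the comparison); returns the observed value, null mean
    and SD, the one-sample t statistic of the replicates against the observed
    value, its two-tailed P, and the Z-score.
    """
    if metric not in nm.METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    observed = nm.metric_on_array(metric, net.array, seed=seed, **metric_kwargs)
    null_vals = np.array([
        nm.metric_on_array(metric, ens.matrices[p], seed=seed + 1 + p,
                           **metric_kwargs)
        for p in range(ens.n_perm)
    ])
    bad = np.isnan(null_vals)
    if bad.mean() > max_undefined_frac:
        raise ValueError(
            f"{metric} undefined on {bad.sum()}/{ens.n_perm} replicates "
            "(degenerate replicate matrices)"
        )
    null_vals = null_vals[~bad]
    mean = float(null_vals.mean())
    sd = float(null_vals.std(ddof=1)) if null_vals.size > 1 else float("nan")
    se = sd / np.sqrt(null_vals.size) if null_vals.size else float("nan")
    if sd == 0:
        t, p = (0.0, 1.0) if observed == mean else (float("inf"), 0.0)
    else:
        t, p = stats.ttest_1samp(null_vals, popmean=observed)
    # add-one two-tailed empirical permutation P: rank of the observed value
    # within the null distribution (the calibrated rejection rule; the t test
    # above gains ensemble-size precision and is reported alongside)
    n = null_vals.size
    ge = ((null_vals >= observed - 1e-12).sum() + 1) / (n + 1)
    le = ((null_vals <= observed + 1e-12).sum() + 1) / (n + 1)
    p_perm = min(1.0, 2.0 * min(ge, le))
    return RandomizationTest(
        metric=metric, observed=float(observed), null_mean=mean, null_sd=sd,
        null_se=float(se), t=float(t), p=float(p), p_perm=float(p_perm),
        z=zscore(observed, mean, sd) if sd == sd else float("nan"),
        n_perm=ens.n_perm,
    )


@dataclass
class NetworkReport:
    """Per-network collection of randomization tests for the index set."""

    network_id: str
    tests: dict[str, RandomizationTest]
    n_perm: int
    seed: int

    @property
    def metrics(self) -> list[str]:
        return list(self.tests)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t in self.tests.items():
            rows.append({"network": self.network_id, "metric": name,
                         "observed": t.observed, "null_mean": t.null_mean,
                         "null_sd": t.null_sd, "null_se": t.null_se,
                         "t": t.t, "p": t.p, "p_perm": t.p_perm, "z": t.z})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame().set_index("metric")
        header = (f"Network architecture report: {self.network_id} "
                  f"({self.n_perm} permutations, seed {self.seed})")
        return header + "\n" + df.to_string(float_format=lambda v: f"{v:.4g}")


def compare_networks(report_a: NetworkReport,
                     report_b: NetworkReport) -> pd.DataFrame:
    """Side-by-side Z-scores for two networks with a sign-based verdict.

    For each index the verdict names which network the Z difference favours
    (e.g. higher H2' Z -> more specialized, lower WNODF Z -> more strongly
    anti-nested); 'tie' when the Z-scores are equal.
    """
    if set(report_a.metrics) != set(report_b.metrics):
        raise ValueError("reports cover different metric sets")
    rows = []
    for metric in report_a.metrics:
        za = report_a.tests[metric].z
        zb = report_b.tests[metric].z
        pos, neg = _VERDICTS.get(metric, ("higher", "lower"))
        if np.isnan(za) or np.isnan(zb) or za == zb:
            verdict = "tie"
        elif zb > za:
            verdict = f"{report_b.network_id} {pos}"
        else:
            verdict = f"{report_b.network_id} {neg}"
        rows.append({"metric": metric,
                     f"z_{report_a.network_id}": za,
                     f"z_{report_b.network_id}": zb,
                     "verdict": verdict})
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

@dataclass
class NetworkArchitectureResults:
    report: NetworkReport

    def summary(self) -> str:
        return self.report.summary()

    def to_frame(self) -> pd.DataFrame:
        return self.report.to_frame()


class NetworkArchitectureModel:
    """Architecture analysis of one compartment's sample-level binary matrix.

    fit() collapses the samples to the species level, builds the
    label-shuffling null ensemble, and runs the randomization test for every
    requested index.
    """

    def __init__(self, binary: BinaryMatrix, network_id: str = "network"):
        self.binary = binary
        self.network_id = network_id

    def fit(self, n_perm: int = 1000, seed: int = 0,
            metrics=DEFAULT_METRICS,
            modularity_optimizer: str = "brim",
            modularity_restarts: int = 6) -> NetworkArchitectureResults:
        spm = to_species_matrix(self.binary)
        # prune absent OTUs but keep every plant row so observed and replicate
        # matrices have identical dimensions (several indices depend on size)
        occupied = spm.data.columns[spm.data.sum(axis=0) > 0]
        net = nm.BipartiteNetwork(spm.data.loc[:, occupied].astype(float))
        pruned = BinaryMatrix(self.binary.data.loc[:, occupied],
                              self.binary.metadata)
        ens = shuffle_labels_ensemble(pruned, n_perm=n_perm, seed=seed)
        tests = {}
        for metric in metrics:
            tests[metric] = randomization_test(
                net, metric, ens, seed=seed,
                modularity_optimizer=modularity_optimizer,
                modularity_restarts=modularity_restarts)
        report = NetworkReport(network_id=self.network_id, tests=tests,
                               n_perm=n_perm, seed=seed)
        return NetworkArchitectureResults(report=report)
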