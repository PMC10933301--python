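"""Modelled larval flow versus observed gene flow, across the ensemble.

Assignment-based gene-flow estimates (BayesAss-style migration rates m)
reflect realised recent dispersal between sampled sites; the dispersal
model provides, for the same ordered site pairs, a whole ensemble of
potential-connectivity values sampling stochastic oceanographic
variability.  This module aligns the two and reports, per ordered pair,
the observed m against the modelled ensemble's feasible range (min-max and
2.5/97.5% quantiles), the log10 ratio of observed to ensemble median, the
pairwise distance, and a flag for pairs whose observation exceeds even the
ensemble maximum.  No demographic conversion is attempted: migration
proportions and settlement probabilities are compared on
orders-of-magnitude terms, which is how the mismatch between realised and
potential connectivity is usually framed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import BootstrapEnsemble, distance_decay, ConnectivityMatrix
from .synthetic_ocean import GeneFlowMatrix, ReefGrid

__all__ = [
    "PairComparisonTable",
    "align_sites",
    "compare_pairs",
    "geneflow_from_ensemble",
]


def align_sites(
    geneflow: GeneFlowMatrix,
    group_labels: np.ndarray,
    mapping: dict[str, int] | None = None,
) -> dict[str, int]:
    """Validated bijection from gene-flow sites onto reef groups.

    Without an explicit mapping, site names of the form ``site_<g>`` or
    plain integers are matched to group ids.  Errors name every unmapped
    site; duplicate target groups are rejected.
    """
    groups = {int(g) for g in group_labels}
    if mapping is None:
        mapping = {}
        for s in geneflow.site_names:
            tail = s.rsplit("_", 1)[-1]
            try:
                mapping[s] = int(tail)
            except ValueError:
                pass
    missing = [s for s in geneflow.site_names if s not in mapping]
    if missing:
        raise ValueError(f"unmapped gene-flow sites: {missing}")
    bad = [s for s in geneflow.site_names if mapping[s] not in groups]
    if bad:
        raise ValueError(
            f"sites mapped to unknown reef groups: {[(s, mapping[s]) for s in bad]}"
        )
    targets = [mapping[s] for s in geneflow.site_names]
    if len(set(targets)) != len(targets):
        dup = [t for t in targets if targets.count(t) > 1]
        raise ValueError(f"duplicate target reef groups: {sorted(set(dup))}")
    return {s: mapping[s] for s in geneflow.site_names}


@dataclass
class PairComparisonTable:
    """Per ordered site pair: observation, modelled ensemble and summaries.

    ``table`` columns: site_i, site_j, observed_m, model_min, model_q025,
    model_median, model_q975, model_max, log10_ratio (observed over
    ensemble median), distance, exceeds_max, outside_95.
    ``ensemble_values[k]`` is the full modelled ensemble for table row k.
    """

    table: pd.DataFrame
    ensemble_values: np.ndarray  # (n_pairs, n_replicates)

    def exceedance_rate(self) -> float:
        return float(self.table["outside_95"].mean())


def compare_pairs(
    ensemble: BootstrapEnsemble,
    geneflow: GeneFlowMatrix,
    mapping: dict[str, int],
    reef: ReefGrid | None = None,
) -> PairComparisonTable:
    """Compare observed migration rates to the modelled ensemble, pairwise.

    Covers every ordered off-diagonal site pair.  The comparison is
    invariant to simultaneously reordering sites in both inputs.
    """
    gindex = {int(g): k for k, g in enumerate(ensemble.labels)}
    site_to_idx = {s: gindex[mapping[s]] for s in geneflow.site_names}

    dist_lookup: dict[tuple[int, int], float] = {}
    if reef is not None:
        mean_mat = ConnectivityMatrix(
            np.clip(ensemble.mean(), 0, None),
            ensemble.labels,
            ensemble.level,
            pd.Timestamp("2000-01-01"),
        )
        dd = distance_decay(mean_mat, reef)
        dist_lookup = {
            (int(r.source), int(r.destination)): float(r.distance)
            for r in dd.itertuples()
        }

    rows = []
    values = []
    sites = geneflow.site_names
    for a, si in enumerate(sites):
        for b, sj in enumerate(sites):
            if a == b:
                continue
            i, j = site_to_idx[si], site_to_idx[sj]
            # observed m[a, b]: fraction of population a derived from b,
            # i.e. flow b -> a; the modelled analogue is C[source=j, dest=i]
            obs = float(geneflow.m[a, b])
            model = ensemble.matrices[:, j, i]
            q025, med, q975 = np.quantile(model, [0.025, 0.5, 0.975])
            mmin, mmax = float(model.min()), float(model.max())
            with np.errstate(divide="ignore"):
                log_ratio = float(np.log10(obs / med)) if obs > 0 and med > 0 else np.inf
            gi, gj = mapping[si], mapping[sj]
            dist = dist_lookup.get((gj, gi), np.nan)
            # a degenerate ensemble collapses the range to a point; treat
            # agreement within round-off as inside the range
            tol = 1e-9 * max(abs(obs), mmax, 1e-300)
            rows.append(
                (
                    si,
                    sj,
                    obs,
                    mmin,
                    float(q025),
                    float(med),
                    float(q975),
                    mmax,
                    log_ratio,
                    dist,
                    obs > mmax + tol,
                    (obs < q025 - tol) or (obs > q975 + tol),
                )
            )
            values.append(model)
    table = pd.DataFrame(
        rows,
        columns=[
            "site_i",
            "site_j",
            "observed_m",
            "model_min",
            "model_q025",
            "model_median",
            "model_q975",
            "model_max",
            "log10_ratio",
            "distance",
            "exceeds_max",
            "outside_95",
        ],
    )
    return PairComparisonTable(table, np.asarray(values))


def geneflow_from_ensemble(
    ensemble: BootstrapEnsemble,
    site_names: list[str] | None = None,
    inflate: np.ndarray | None = None,
) -> GeneFlowMatrix:
    """Synthetic migration-rate matrix simulated *from* the modelled ensemble.

    A closed-loop observation: off-diagonal entries are the ensemble-mean
    connectivity (transposed into the migration-rate orientation, m[i, j] =
    flow j -> i), optionally multiplied elementwise by ``inflate``, and the
    diagonal absorbs the remaining row mass so rows sum to 1 (potential
    connectivity is tiny, so self-recruitment comes out high, as
    assignment methods report).  Used to test that observations generated
    by the model itself fall inside the model's feasible range.
    """
    mean = ensemble.mean()
    n = mean.shape[0]
    m = mean.T.copy()
    np.fill_diagonal(m, 0.0)
    if inflate is not None:
        m = m * np.asarray(inflate, dtype=float)
    off_sums = m.sum(axis=1)
    if np.any(off_sums >= 1.0):
        raise ValueError("ensemble connectivity too large to renormalise into rates")
    m += np.diag(1.0 - off_sums)
    names = site_names or [f"site_{int(g)}" for g in ensemble.labels]
    return GeneFlowMatrix(list(names), m)
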