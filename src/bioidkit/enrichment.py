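"""Ciliated-versus-cycling differential enrichment of prey spectral counts.

For each prey of one bait, the fold change is the ratio of replicate-average
spectral counts between the two conditions (with a pseudocount keeping it
finite and symmetric), and significance is a two-sided Welch t test on
log(count + 1).  Preys are classified for a volcano plot as increased
(FC >= 2 and p < 0.05), decreased (FC <= 0.5 and p < 0.05) or unchanged.
No multiple-testing correction is applied to the classification (the raw
p < 0.05 volcano convention); a Benjamini-Hochberg column is emitted
alongside for users who want it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .experiment import SpectralCountExperiment, ValidationError


def fold_change(ciliated_counts, cycling_counts, pseudocount: float = 0.5) -> float:
    """(mean ciliated + pseudocount) / (mean cycling + pseudocount)."""
    c = np.asarray(ciliated_counts, dtype=float)
    n = np.asarray(cycling_counts, dtype=float)
    if c.size == 0 or n.size == 0:
        raise ValidationError("both conditions need at least one replicate")
    return float((c.mean() + pseudocount) / (n.mean() + pseudocount))


def enrichment_test(ciliated_counts, cycling_counts) -> float:
    """Two-sided Welch t test on log(count+1); p = 1 when it cannot be run.

    With fewer than two replicates in either condition, or with zero
    variance on both sides (e.g. identical vectors), there is no evidence
    either way and the test returns 1 by contract.
    """
    c = np.log1p(np.asarray(ciliated_counts, dtype=float))
    n = np.log1p(np.asarray(cycling_counts, dtype=float))
    if c.size < 2 or n.size < 2:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant groups trigger a precision warning; the nan result is
        # mapped to the degenerate p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(c, n, equal_var=False)
    if not np.isfinite(p):
        return 1.0
    return float(p)


def classify(
    results: pd.DataFrame, fc_threshold: float = 2.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Fill the volcano class and derived plotting columns.

    Expects columns ``fold_change`` and ``p_value``; adds ``log2_fc``,
    ``neg_log10_p`` and ``class`` (increased / decreased / unchanged).
    """
    out = results.copy()
    fc = out["fold_change"].to_numpy(dtype=float)
    p = out["p_value"].to_numpy(dtype=float)
    cls = np.full(len(out), "unchanged", dtype=object)
    sig = p < alpha
    cls[sig & (fc >= fc_threshold)] = "increased"
    cls[sig & (fc <= 1.0 / fc_threshold)] = "decreased"
    out["log2_fc"] = np.log2(fc)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(p)
    out["class"] = cls
    return out


def compare_conditions(
    experiment: SpectralCountExperiment,
    bait_id: str,
    pseudocount: float = 0.5,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Volcano table for one bait: every prey detected in either condition."""
    cil_runs = experiment.runs_for(bait_id, "ciliated")
    cyc_runs = experiment.runs_for(bait_id, "cycling")
    if not cil_runs or not cyc_runs:
        raise ValidationError(
            f"bait {bait_id!r} needs runs in both the ciliated and cycling conditions"
        )
    cil = experiment.counts_for_runs(cil_runs)
    cyc = experiment.counts_for_runs(cyc_runs)
    detected = sorted(
        experiment.detected_preys(bait_id, "ciliated")
        | experiment.detected_preys(bait_id, "cycling")
    )
    rows = []
    for prey in detected:
        c = cil[prey].to_numpy()
        n = cyc[prey].to_numpy()
        rows.append(
            {
                "bait_id": bait_id,
                "prey_id": prey,
                "avg_ciliated": float(c.mean()),
                "avg_cycling": float(n.mean()),
                "fold_change": fold_change(c, n, pseudocount),
                "p_value": enrichment_test(c, n),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return classify(table, fc_threshold=fc_threshold, alpha=alpha)
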