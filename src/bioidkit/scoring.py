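"""SAINT-style interaction scoring against compressed virtual controls.

Each bait-prey pair is scored by comparing the prey's spectral counts in the
bait's replicate runs against a background estimated from negative-control
runs.  Control runs are first *compressed* to ``k`` virtual controls: for
every prey, only its ``k`` highest control counts are retained (zero-padded
when fewer controls exist), which makes the background estimate — and hence
the scoring — deliberately stringent.

The probability model is a two-component count mixture evaluated per
replicate:

* background component: negative binomial with mean ``mu0 = max(mean of the
  virtual controls, background_floor)``;
* true-interaction component: negative binomial with mean
  ``mu1 = max(mean of the test counts, min_fold * mu0)``;
* equal prior odds by default.

Both components are negative binomial with a shared size parameter
(``dispersion``), i.e. variance mu + mu^2/size — Poisson sampling plus
multiplicative between-replicate noise of CV 1/sqrt(size); ``math.inf``
gives the Poisson limit.  The per-replicate posterior probability of a
true interaction is averaged across biological replicates (AvgP), and a
Bayesian false discovery rate (BFDR) is obtained as the cumulative mean of
``1 - AvgP`` down the AvgP-ranked list of one bait's preys.  No claim of
bit-compatibility with any external scorer is made; the contract is the
thresholding behaviour: control-like preys fail, strongly enriched preys
pass at BFDR <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import nbinom, poisson

from .experiment import SpectralCountExperiment, ValidationError


@dataclass(frozen=True)
class ScoringModel:
    """Parameters of the two-component count mixture.

    background_floor
        Minimum background mean in counts; keeps the model defined when a
        prey was never seen in any control.
    min_fold
        The true-interaction mean is at least this multiple of the
        background mean, so the alternative is always an *enrichment*.
    dispersion
        Negative-binomial size of both components (variance
        mu + mu^2/size); 10 corresponds to ~32% between-replicate CV, a
        typical reproducibility level for spectral counts.  ``math.inf``
        gives the Poisson limit.
    prior_log_odds
        log(P(true)/P(background)); 0 = equal prior odds.
    """

    background_floor: float = 0.1
    min_fold: float = 2.0
    dispersion: float = 10.0
    prior_log_odds: float = 0.0


DEFAULT_MODEL = ScoringModel()


@dataclass(frozen=True)
class VirtualControlSet:
    """The k highest control counts for one prey, in descending order."""

    prey_id: str
    compressed_counts: tuple[int, ...]

    def __post_init__(self):
        cc = tuple(int(c) for c in self.compressed_counts)
        if any(c < 0 for c in cc):
            raise ValidationError("virtual control counts must be non-negative")
        if list(cc) != sorted(cc, reverse=True):
            raise ValidationError("virtual control counts must be descending")
        object.__setattr__(self, "compressed_counts", cc)

    @property
    def mean(self) -> float:
        return float(np.mean(self.compressed_counts))


@dataclass
class ScoredInteraction:
    """One bait-prey pair with replicate probabilities, AvgP and BFDR."""

    bait_id: str
    prey_id: str
    replicate_counts: list[int]
    replicate_probabilities: list[float]
    avg_p: float
    avg_spec: float
    ctrl_counts: list[int]
    ctrl_avg: float
    bfdr: float = float("nan")
    condition: str | None = None

    @property
    def dataset(self) -> str:
        return self.bait_id if self.condition is None else f"{self.bait_id}|{self.condition}"


# ----------------------------------------------------------------------


def compress_controls(
    experiment: SpectralCountExperiment,
    k: int = 4,
    condition: str | None = None,
) -> dict[str, VirtualControlSet]:
    """Compress the control runs to k virtual controls per prey.

    For every prey the k largest control counts are kept, in descending
    order, zero-padded when fewer than k control runs exist.  With
    ``condition`` given, only condition-matched controls are used.
    """
    if k < 1:
        raise ValidationError("k must be a positive integer")
    runs = experiment.control_runs(condition)
    if not runs:
        raise ValidationError(
            "no control runs"
            + (f" for condition {condition!r}" if condition else "")
        )
    mat = _compress_matrix(experiment.counts_for_runs(runs).to_numpy(), k)
    return {
        prey: VirtualControlSet(prey, tuple(int(c) for c in mat[j]))
        for j, prey in enumerate(experiment.prey_ids)
    }


def _compress_matrix(control_counts: np.ndarray, k: int) -> np.ndarray:
    """(n_runs, n_preys) control counts -> (n_preys, k) top-k, descending."""
    n_runs, n_preys = control_counts.shape
    if n_runs < k:
        padded = np.zeros((k, n_preys), dtype=control_counts.dtype)
        padded[:n_runs] = control_counts
        control_counts = padded
    top = -np.sort(-control_counts, axis=0)[:k]
    return top.T


# ----------------------------------------------------------------------


def _log_pmf(k: np.ndarray, mu: np.ndarray, size: float) -> np.ndarray:
    if not np.isfinite(size):
        return poisson.logpmf(k, mu)
    return nbinom.logpmf(k, size, size / (size + mu))


def _score_matrix(
    test_counts: np.ndarray, ctrl_mean: np.ndarray, model: ScoringModel
) -> np.ndarray:
    """Posterior P(true) for a (n_preys, n_reps) count matrix."""
    mu0 = np.maximum(np.asarray(ctrl_mean, dtype=float), model.background_floor)
    mu1 = np.maximum(test_counts.mean(axis=1), model.min_fold * mu0)
    ll0 = _log_pmf(test_counts, mu0[:, None], model.dispersion)
    ll1 = _log_pmf(test_counts, mu1[:, None], model.dispersion)
    return expit(ll1 - ll0 + model.prior_log_odds)


def score_pair(
    test_counts,
    controls,
    model: ScoringModel = DEFAULT_MODEL,
) -> np.ndarray:
    """Per-replicate posterior probability of a true interaction.

    ``controls`` may be a :class:`VirtualControlSet` or any sequence of
    compressed control counts.  The probability is monotone non-decreasing
    in the test count with controls held fixed.
    """
    counts = np.asarray(test_counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValidationError("at least one test count is required")
    if (counts < 0).any():
        raise ValidationError("test counts must be non-negative")
    if isinstance(controls, VirtualControlSet):
        ctrl_mean = controls.mean
    else:
        ctrl_mean = float(np.mean(np.asarray(controls, dtype=float)))
    probs = _score_matrix(counts[None, :], np.array([ctrl_mean]), model)
    return probs[0]


# ----------------------------------------------------------------------


def compute_bfdr(scored: list[ScoredInteraction]) -> list[ScoredInteraction]:
    """Fill BFDR per bait dataset; returns records sorted by descending AvgP.

    Within each (bait, condition) dataset records are ranked by descending
    AvgP and the BFDR at rank r is the cumulative mean of ``1 - AvgP`` over
    the top r records.  Records tied on AvgP all receive the worst (largest)
    BFDR of their tie block, so thresholding does not depend on tie order.
    """
    if not scored:
        raise ValidationError("cannot compute BFDR of an empty record list")
    groups: dict[str, list[ScoredInteraction]] = {}
    for s in scored:
        groups.setdefault(s.dataset, []).append(s)
    out: list[ScoredInteraction] = []
    for key in sorted(groups):
        recs = sorted(groups[key], key=lambda s: (-s.avg_p, s.prey_id))
        p = np.array([s.avg_p for s in recs])
        raw = np.cumsum(1.0 - p) / np.arange(1, len(p) + 1)
        # worst-of-block for ties on AvgP
        bfdr = raw.copy()
        i = 0
        while i < len(p):
            j = i
            while j + 1 < len(p) and p[j + 1] == p[i]:
                j += 1
            bfdr[i : j + 1] = raw[j]
            i = j + 1
        for s, b in zip(recs, bfdr):
            s.bfdr = float(b)
        out.extend(recs)
    return out


def score_experiment(
    experiment: SpectralCountExperiment,
    k: int = 4,
    model: ScoringModel = DEFAULT_MODEL,
    by_condition: bool = False,
) -> list[ScoredInteraction]:
    """Score every detected bait-prey pair and compute BFDRs.

    Each (bait, condition) replicate group is scored as one dataset.  By
    default all control runs are pooled before virtual-control compression;
    with ``by_condition=True`` every dataset is scored against
    condition-matched controls only.  Only preys detected with the bait
    (nonzero count in at least one replicate) are scored.
    """
    prey_ids = np.array(experiment.prey_ids)
    vc_pooled = None
    if not by_condition:
        vc_pooled = _vc_matrix(experiment, k, None)
    scored: list[ScoredInteraction] = []
    for bait in experiment.test_baits:
        for condition in experiment.conditions_for(bait):
            runs = experiment.runs_for(bait, condition)
            M = experiment.counts_for_runs(runs).to_numpy().T  # preys x reps
            detected = (M > 0).any(axis=1)
            if not detected.any():
                continue
            vc = (
                _vc_matrix(experiment, k, condition) if by_condition else vc_pooled
            )
            Md = M[detected].astype(float)
            vcd = vc[detected]
            probs = _score_matrix(Md, vcd.mean(axis=1), model)
            for prey, row, prow, ctrl in zip(
                prey_ids[detected], Md, probs, vcd, strict=True
            ):
                scored.append(
                    ScoredInteraction(
                        bait_id=bait,
                        prey_id=str(prey),
                        replicate_counts=[int(c) for c in row],
                        replicate_probabilities=[float(p) for p in prow],
                        avg_p=float(prow.mean()),
                        avg_spec=float(row.mean()),
                        ctrl_counts=[int(c) for c in ctrl],
                        ctrl_avg=float(ctrl.mean()),
                        condition=condition,
                    )
                )
    if not scored:
        raise ValidationError("no detected bait-prey pairs to score")
    return compute_bfdr(scored)


def _vc_matrix(
    experiment: SpectralCountExperiment, k: int, condition: str | None
) -> np.ndarray:
    runs = experiment.control_runs(condition)
    if not runs:
        raise ValidationError(
            "no control runs"
            + (f" for condition {condition!r}" if condition else "")
        )
    return _compress_matrix(experiment.counts_for_runs(runs).to_numpy(), k)
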