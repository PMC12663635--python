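"""High-confidence interactome selection.

Every bait dataset is first thresholded at BFDR <= 0.01.  For designated
baits two additional manual filters apply, in a fixed order:

1. partner rescue — a prey detected with the bait that is high-confidence in
   a partner bait's dataset is kept even if it missed the BFDR cut (rescue
   never imports preys that were not observed with the bait);
2. control-bait exclusion — a prey whose average spectral count in a
   dedicated negative-control bait dataset is ``ratio`` times (default 4x)
   its average with the bait, or more, is dropped.

Exclusion runs last so that control-sticky preys cannot re-enter via rescue.
Gene identifiers are compared case-insensitively (human gene-symbol
convention) but reported with their original case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .experiment import ValidationError
from .scoring import ScoredInteraction

#: bait averages are floored at one spectral count spread over four virtual
#: control slots, so the exclusion ratio is defined for undetected preys
BAIT_AVG_FLOOR = 0.25


@dataclass
class FilterReport:
    """Accounting of one bait's filtering with a per-prey decision trail."""

    bait_id: str
    input_n: int = 0
    pass_bfdr: int = 0
    rescued_by_partner: int = 0
    excluded_by_control: int = 0
    final_n: int = 0
    trail: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def terminal_decision(self, prey_id: str) -> str:
        return self.trail[prey_id][-1][1]

    def reconcile(self) -> None:
        kept = sum(1 for p in self.trail if self.terminal_decision(p) == "keep")
        if kept != self.final_n:
            raise ValidationError(
                f"{self.bait_id}: final_n {self.final_n} != kept decisions {kept}"
            )
        if self.final_n != self.pass_bfdr + self.rescued_by_partner - self.excluded_by_control:
            raise ValidationError(f"{self.bait_id}: filter counts do not reconcile")


@dataclass(frozen=True)
class FilterPlan:
    """Which filters apply to which bait dataset.

    rescue_partners maps a bait to the partner bait whose high-confidence
    set rescues sub-threshold detections; control_baits maps a bait to the
    negative-control bait used for the enrichment exclusion.
    """

    bfdr_threshold: float = 0.01
    rescue_partners: Mapping[str, str] = field(default_factory=dict)
    control_baits: Mapping[str, str] = field(default_factory=dict)
    control_ratio: float = 4.0


def _upper(s: str) -> str:
    return s.upper()


def filter_bfdr(scored: Iterable[ScoredInteraction], threshold: float = 0.01) -> set[str]:
    """Preys kept at the BFDR cutoff (inclusive: bfdr <= threshold)."""
    return {s.prey_id for s in scored if s.bfdr <= threshold}


def rescue_by_partner(
    candidate_preys: set[str],
    partner_high_confidence: set[str],
    detected_preys: set[str],
) -> tuple[set[str], set[str]]:
    """Add bait-detected preys that are high-confidence with the partner bait.

    Returns (augmented set, the rescued preys).  Comparison is
    case-insensitive; only preys in ``detected_preys`` can be rescued.
    """
    partner_u = {_upper(p) for p in partner_high_confidence}
    candidate_u = {_upper(p) for p in candidate_preys}
    rescued = {
        p
        for p in detected_preys
        if _upper(p) in partner_u and _upper(p) not in candidate_u
    }
    return candidate_preys | rescued, rescued


def exclude_control_enriched(
    candidate_preys: set[str],
    bait_avg: Mapping[str, float],
    control_bait_avg: Mapping[str, float],
    ratio: float = 4.0,
    floor: float = BAIT_AVG_FLOOR,
) -> tuple[set[str], set[str]]:
    """Drop preys enriched ``ratio``-fold or more in the control-bait dataset.

    A prey is excluded iff control_avg >= ratio * max(bait_avg, floor); the
    floor keeps the ratio defined when the prey was not counted with the
    bait.  Returns (kept, excluded).
    """
    ctrl_u = {_upper(k): v for k, v in control_bait_avg.items()}
    bait_u = {_upper(k): v for k, v in bait_avg.items()}
    excluded = set()
    for prey in candidate_preys:
        b = max(bait_u.get(_upper(prey), 0.0), floor)
        c = ctrl_u.get(_upper(prey), 0.0)
        if c >= ratio * b:
            excluded.add(prey)
    return candidate_preys - excluded, excluded


def _by_bait(scored: Iterable[ScoredInteraction]) -> dict[str, list[ScoredInteraction]]:
    out: dict[str, list[ScoredInteraction]] = {}
    for s in scored:
        out.setdefault(s.bait_id, []).append(s)
    return out


def _best_records(records: list[ScoredInteraction]) -> dict[str, ScoredInteraction]:
    """Per prey, the record with the smallest BFDR (conditions merged)."""
    best: dict[str, ScoredInteraction] = {}
    for s in records:
        cur = best.get(s.prey_id)
        if cur is None or s.bfdr < cur.bfdr:
            best[s.prey_id] = s
    return best


def _avg_map(records: list[ScoredInteraction]) -> dict[str, float]:
    """Per prey, the maximum replicate-average spectral count across conditions."""
    out: dict[str, float] = {}
    for s in records:
        out[s.prey_id] = max(out.get(s.prey_id, 0.0), s.avg_spec)
    return out


def build_high_confidence(
    scored: Iterable[ScoredInteraction],
    plan: FilterPlan = FilterPlan(),
) -> tuple[dict[str, set[str]], dict[str, FilterReport]]:
    """Apply the filtering plan to every bait; returns kept sets and reports.

    The BFDR filter applies to every bait (a prey passes if any of its
    condition datasets passes); partner rescue and control-bait exclusion
    apply only to baits the plan designates, in the order
    BFDR -> rescue -> exclude.
    """
    groups = _by_bait(scored)
    known = set(groups)
    for mapping in (plan.rescue_partners, plan.control_baits):
        for bait, other in mapping.items():
            if bait not in known or other not in known:
                raise ValidationError(
                    f"filter plan references unknown bait: {bait!r} -> {other!r}"
                )
    kept_sets: dict[str, set[str]] = {}
    reports: dict[str, FilterReport] = {}
    hc_cache: dict[str, set[str]] = {
        bait: filter_bfdr(recs, plan.bfdr_threshold) for bait, recs in groups.items()
    }
    for bait, recs in groups.items():
        best = _best_records(recs)
        detected = set(best)
        report = FilterReport(bait_id=bait, input_n=len(detected))
        kept = hc_cache[bait] & detected
        report.pass_bfdr = len(kept)
        for prey in sorted(detected):
            report.trail[prey] = [("bfdr", "pass" if prey in kept else "fail")]
        partner = plan.rescue_partners.get(bait)
        if partner is not None:
            kept, rescued = rescue_by_partner(kept, hc_cache[partner], detected)
            report.rescued_by_partner = len(rescued)
            for prey in rescued:
                report.trail[prey].append(("partner_rescue", "rescued"))
        ctrl_bait = plan.control_baits.get(bait)
        if ctrl_bait is not None:
            kept, excluded = exclude_control_enriched(
                kept,
                _avg_map(recs),
                _avg_map(groups[ctrl_bait]),
                ratio=plan.control_ratio,
            )
            report.excluded_by_control = len(excluded)
            for prey in excluded:
                report.trail[prey].append(("control_ratio", "excluded"))
        for prey in report.trail:
            report.trail[prey].append(
                ("final", "keep" if prey in kept else "drop")
            )
        report.final_n = len(kept)
        report.reconcile()
        kept_sets[bait] = kept
        reports[bait] = report
    return kept_sets, reports
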