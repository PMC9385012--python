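"""Sample-adequacy quality control and the cohort exclusion cascade.

A sputum sample is analyzable only if it demonstrably originates from the
lung and carries enough cells for a stable profile.  Four rules, all
inclusive (a value meeting the threshold passes):

* at least 1.5e6 total cells counted before antibody staining;
* at least 1000 CD45+ events acquired (leukocyte tube);
* combined alveolar + interstitial macrophages (gates 2+3) at least 0.05%
  of live single events — five macrophages per 10,000 cells;
* at least one alveolar macrophage event (interstitial macrophages without
  alveolar ones are biologically ambiguous).

The module also computes FMO background statistics (mean, SD, mean + 2 SD —
the background-derived alternative to the 0.05% rule) and tallies the
per-study exclusion cascade from intake to the finally analyzed cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .errors import LedgerError, MissingMetadataError
from .pipeline import SampleResult

__all__ = [
    "QCThresholds",
    "QCReport",
    "ExclusionLedger",
    "CascadeSummary",
    "evaluate_adequacy",
    "assess_adequacy",
    "fmo_background_stats",
    "mean_plus_2sd",
    "exclusion_cascade",
    "macrophages_per",
    "round_half_up",
    "LEDGER_CATEGORIES",
]

LEDGER_CATEGORIES = (
    "eligible_analyzed",
    "ineligible",
    "status_unconfirmed",
    "technical_failure",
    "too_few_cells",
    "too_few_macrophages",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up, the convention used for report percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def macrophages_per(pct: float, per: int = 10_000) -> float:
    """Expected macrophage count implied by a percentage cutoff.

    The 0.05% adequacy cutoff corresponds to 5 macrophages per 10,000 cells.
    """
    return pct / 100.0 * per


@dataclass(frozen=True)
class QCThresholds:
    min_cells_prestain: float = 1.5e6
    min_cd45_events: int = 1000
    min_macrophage_pct: float = 0.05
    #: denominator for the macrophage percentage: "live_singles" (default) or
    #: "cd45pos" — the published rule does not name one; live single events
    #: match a per-10,000-analyzable-cells reading
    macrophage_denominator: str = "live_singles"


@dataclass
class QCReport:
    sample_id: str
    total_cells_prestain: float
    n_live_singles: int
    n_cd45pos_events: int
    pct_macrophage: float
    has_alveolar: bool
    verdict: str  # adequate | inadequate
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.verdict == "adequate") != (not self.reasons):
            raise ValueError("verdict must be 'adequate' iff reasons is empty")


def evaluate_adequacy(
    total_cells_prestain: float,
    n_cd45pos_events: int,
    pct_macrophage: float,
    has_alveolar: bool,
    thresholds: QCThresholds = QCThresholds(),
) -> list[str]:
    """Return the list of failed rules (empty means adequate)."""
    reasons = []
    if total_cells_prestain < thresholds.min_cells_prestain:
        reasons.append("too_few_cells_prestain")
    if n_cd45pos_events < thresholds.min_cd45_events:
        reasons.append("too_few_cd45_events")
    if math.isnan(pct_macrophage) or pct_macrophage < thresholds.min_macrophage_pct:
        reasons.append("too_few_macrophages")
    if not has_alveolar:
        reasons.append("no_alveolar_macrophages")
    return reasons


def assess_adequacy(
    result: SampleResult,
    meta: Mapping[str, object],
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Adequacy verdict for one analyzed sample.

    ``meta`` must carry ``total_cells_prestain`` (the pre-stain hemocytometer
    count); gate counts come from the sample's own gating result.
    """
    if "total_cells_prestain" not in meta or meta["total_cells_prestain"] is None:
        raise MissingMetadataError(
            f"sample {result.sample_id!r}: pre-stain cell count missing; QC impossible"
        )
    prestain = float(meta["total_cells_prestain"])  # type: ignore[arg-type]
    counts = result.node_counts.get("leukocyte", {})
    n_live = counts.get("live", 0)
    n_cd45 = counts.get("cd45pos", 0)
    n_mac = counts.get("gate2", 0) + counts.get("gate3", 0)
    if thresholds.macrophage_denominator == "cd45pos":
        den = n_cd45
    else:
        den = n_live
    pct_mac = 100.0 * n_mac / den if den else float("nan")
    reasons = evaluate_adequacy(
        prestain, n_cd45, pct_mac, counts.get("gate2", 0) >= 1, thresholds
    )
    return QCReport(
        sample_id=result.sample_id,
        total_cells_prestain=prestain,
        n_live_singles=n_live,
        n_cd45pos_events=n_cd45,
        pct_macrophage=pct_mac,
        has_alveolar=counts.get("gate2", 0) >= 1,
        verdict="adequate" if not reasons else "inadequate",
        reasons=reasons,
    )


# ---------------------------------------------------------------------------
# FMO background statistics
# ---------------------------------------------------------------------------

def mean_plus_2sd(mean: float, sd: float) -> float:
    """Background positivity threshold: mean + 2 standard deviations."""
    return mean + 2.0 * sd


def fmo_background_stats(background_pcts: Sequence[float]) -> dict[str, float]:
    """Mean, sample SD and mean + 2 SD of per-sample FMO background rates.

    A single observation leaves the SD (and hence the threshold) undefined.
    """
    x = np.asarray(list(background_pcts), dtype=float)
    if x.size == 0:
        raise ValueError("background list must be non-empty")
    mean = float(np.mean(x))
    if x.size == 1:
        return {"mean": mean, "sd": float("nan"), "mean_plus_2sd": float("nan")}
    sd = float(np.std(x, ddof=1))
    return {"mean": mean, "sd": sd, "mean_plus_2sd": mean_plus_2sd(mean, sd)}


# ---------------------------------------------------------------------------
# Exclusion cascade
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLedger:
    """Per-sample disposition of a study cohort.

    ``categories`` maps sample id to exactly one ledger category;
    ``groups`` labels the analyzed samples (cancer / high_risk).
    """

    categories: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, cat in self.categories.items():
            if cat not in LEDGER_CATEGORIES:
                raise LedgerError(f"sample {sid!r}: unknown category {cat!r}")

    @classmethod
    def from_counts(
        cls,
        ineligible: int = 0,
        status_unconfirmed: int = 0,
        technical_failure: int = 0,
        too_few_cells: int = 0,
        too_few_macrophages: int = 0,
        analyzed_groups: Mapping[str, int] = (),
    ) -> "ExclusionLedger":
        """Build a ledger from category totals (synthetic sample ids)."""
        categories: dict[str, str] = {}
        groups: dict[str, str] = {}
        i = 0
        for cat, n in [
            ("ineligible", ineligible),
            ("status_unconfirmed", status_unconfirmed),
            ("technical_failure", technical_failure),
            ("too_few_cells", too_few_cells),
            ("too_few_macrophages", too_few_macrophages),
        ]:
            for _ in range(int(n)):
                categories[f"S{i:04d}"] = cat
                i += 1
        for group, n in dict(analyzed_groups).items():
            for _ in range(int(n)):
                sid = f"S{i:04d}"
                categories[sid] = "eligible_analyzed"
                groups[sid] = group
                i += 1
        return cls(categories, groups)


@dataclass
class CascadeSummary:
    n_intake: int
    n_initial_excluded: int
    n_flow_analyzed: int
    n_final: int
    category_counts: dict[str, int]
    group_counts: dict[str, int]
    pct_too_few_cells_of_flow: float
    pct_too_few_macrophages_of_flow: float


def exclusion_cascade(ledger: ExclusionLedger) -> CascadeSummary:
    """Summarize intake -> flow-analyzed -> finally analyzed counts.

    Initial exclusions (ineligibility, unconfirmed status, technical
    failure) precede flow analysis; adequacy exclusions (too few cells /
    macrophages) come out of the flow-analyzed set.  Report percentages use
    the flow-analyzed denominator, rounded half-up to one decimal.
    """
    counts = {cat: 0 for cat in LEDGER_CATEGORIES}
    for cat in ledger.categories.values():
        counts[cat] += 1
    n_intake = len(ledger.categories)
    n_initial = (
        counts["ineligible"] + counts["status_unconfirmed"] + counts["technical_failure"]
    )
    n_flow = n_intake - n_initial
    n_final = n_flow - counts["too_few_cells"] - counts["too_few_macrophages"]
    if n_final != counts["eligible_analyzed"]:
        raise LedgerError(
            f"ledger totals inconsistent: {n_final} expected analyzed, "
            f"{counts['eligible_analyzed']} categorized as analyzed"
        )
    group_counts: dict[str, int] = {}
    for sid, cat in ledger.categories.items():
        if cat == "eligible_analyzed":
            g = ledger.groups.get(sid, "unlabeled")
            group_counts[g] = group_counts.get(g, 0) + 1
    pct_cells = round_half_up(100.0 * counts["too_few_cells"] / n_flow, 1) if n_flow else float("nan")
    pct_mac = round_half_up(100.0 * counts["too_few_macrophages"] / n_flow, 1) if n_flow else float("nan")
    return CascadeSummary(
        n_intake=n_intake,
        n_initial_excluded=n_initial,
        n_flow_analyzed=n_flow,
        n_final=n_final,
        category_counts=counts,
        group_counts=group_counts,
        pct_too_few_cells_of_flow=pct_cells,
        pct_too_few_macrophages_of_flow=pct_mac,
    )
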