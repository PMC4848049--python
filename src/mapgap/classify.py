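"""Lesion-integrity classification from per-site detection results.

Decision rules, applied post-ablation at each surveyed site:

* a MAP at a site inside the intended lesion pattern ⇒ conduction **gap**;
* a MAP outside the pattern ⇒ **conductive** (viable, non-ablated tissue);
* no MAP while the applied contact force strictly exceeded the reference
  force (the site's own pre-ablation detection force when available,
  otherwise the cohort mean of viable tissue) ⇒ **non-conductive**;
* no MAP without a proven supra-reference force ⇒ **indeterminate** — the
  absence of a MAP is only meaningful when tissue contact was at least as
  firm as what viable tissue needs, so an under-probed site is never called
  non-conductive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .detection import DetectionResult
from .errors import EmptyReferenceError

log = logging.getLogger(__name__)


class Label(str, Enum):
    CONDUCTIVE = "conductive"
    NON_CONDUCTIVE = "non_conductive"
    GAP = "gap"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ReferenceThreshold:
    """Cohort contact-force reference for viable tissue (grams)."""

    mean_cf: float
    sd_cf: float
    n: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("reference needs n >= 1")
        if self.mean_cf <= 0 or self.sd_cf < 0:
            raise ValueError("reference moments out of range")


#: cohort reference measured pre-ablation on viable epicardial ventricular
#: septum (>200 MAP points): mean contact force 7.6 g, SD 4.4 g.
EPICARDIAL_SEPTUM_REFERENCE = ReferenceThreshold(
    mean_cf=7.6, sd_cf=4.4, n=200, source="pre-ablation epicardial ventricular septum survey"
)


@dataclass
class SiteAssessment:
    """One catheter application at one anatomic site.

    Scalar summary fields (``map_present``, ``cf_at_detection``,
    ``max_cf_applied``) drive classification; ``detection`` carries the full
    per-beat result when the assessment came from a raw trace. Surveys whose
    negatives are only known to have been probed "above the reference force"
    (no printed value) set ``supra_reference_force`` instead of a number.
    """

    site_id: str
    phase: str  # "pre_ablation" | "post_ablation"
    in_lesion_pattern: bool
    map_present: bool
    cf_at_detection: Optional[float] = None  # grams, at the qualifying run
    max_cf_applied: Optional[float] = None  # grams
    supra_reference_force: bool = False
    pre_ablation_cf: Optional[float] = None  # site-matched reference, grams
    detection: Optional[DetectionResult] = None

    def __post_init__(self) -> None:
        if self.phase not in ("pre_ablation", "post_ablation"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @classmethod
    def from_detection(
        cls,
        site_id: str,
        phase: str,
        in_lesion_pattern: bool,
        detection: DetectionResult,
        pre_ablation_cf: Optional[float] = None,
    ) -> "SiteAssessment":
        return cls(
            site_id=site_id,
            phase=phase,
            in_lesion_pattern=in_lesion_pattern,
            map_present=detection.map_present,
            cf_at_detection=detection.cf_at_detection,
            max_cf_applied=detection.max_cf_applied,
            pre_ablation_cf=pre_ablation_cf,
            detection=detection,
        )


@dataclass
class SiteClassification:
    site_id: str
    label: Label
    rationale: str
    cf_reference_used: Optional[float] = None  # grams
    cf_evidence: Optional[float] = None  # grams


def build_reference(pre_assessments: list[SiteAssessment], source: str = "") -> ReferenceThreshold:
    """Cohort reference from pre-ablation assessments: mean and sample SD of
    the contact force at first sustained MAP detection.

    Assessments without a detection (no qualifying run) are excluded and
    logged; the SD uses the n-1 denominator and is 0 for a singleton.
    """
    cfs = []
    for a in pre_assessments:
        if a.cf_at_detection is not None:
            cfs.append(a.cf_at_detection)
        else:
            log.info("reference: excluding site %s (no MAP detected)", a.site_id)
    if not cfs:
        raise EmptyReferenceError("no pre-ablation assessment with a detected MAP")
    arr = np.asarray(cfs, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return ReferenceThreshold(mean_cf=float(arr.mean()), sd_cf=sd, n=len(arr), source=source)


def classify_site(
    assessment: SiteAssessment,
    reference: ReferenceThreshold,
    reference_mode: str = "site_matched_first",
) -> SiteClassification:
    """Label one post-ablation site per the decision rules.

    The reference force is the site-matched pre-ablation CF when available
    (and ``reference_mode`` allows it), with the cohort mean as fallback.
    The force comparison is strict (>); ties fall to indeterminate.
    """
    if assessment.phase != "post_ablation":
        raise ValueError("classification applies to post-ablation assessments")
    if reference_mode == "site_matched_first" and assessment.pre_ablation_cf is not None:
        ref = assessment.pre_ablation_cf
    else:
        ref = reference.mean_cf

    if assessment.map_present:
        evidence = (
            assessment.cf_at_detection
            if assessment.cf_at_detection is not None
            else assessment.max_cf_applied
        )
        if assessment.in_lesion_pattern:
            label = Label.GAP
            why = "MAP detected inside the lesion pattern: residual viable tissue"
        else:
            label = Label.CONDUCTIVE
            why = "MAP detected outside the lesion pattern: non-ablated myocardium"
    else:
        evidence = assessment.max_cf_applied
        exceeded = assessment.supra_reference_force or (
            assessment.max_cf_applied is not None and assessment.max_cf_applied > ref
        )
        if exceeded:
            label = Label.NON_CONDUCTIVE
            why = "no MAP although applied force exceeded the reference"
        else:
            label = Label.INDETERMINATE
            why = "no MAP but sufficient contact was never demonstrated"
    cls = SiteClassification(
        site_id=assessment.site_id,
        label=label,
        rationale=why,
        cf_reference_used=ref,
        cf_evidence=evidence,
    )
    log.info("site %s -> %s (%s)", assessment.site_id, label.value, why)
    return cls


# ------------------------------------------------------------------ reporting

@dataclass
class SurveyReport:
    """Aggregated classification of a surveyed lesion pattern."""

    classifications: list[SiteClassification]
    counts: dict  # label -> count, split by pattern membership
    gap_sites: list[str]
    n_map_positive: int
    reference: Optional[ReferenceThreshold] = None

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "gap_sites": self.gap_sites,
            "n_sites": len(self.classifications),
            "n_map_positive": self.n_map_positive,
            "reference": None
            if self.reference is None
            else {
                "mean_cf": self.reference.mean_cf,
                "sd_cf": self.reference.sd_cf,
                "n": self.reference.n,
                "source": self.reference.source,
            },
            "sites": [
                {
                    "site_id": c.site_id,
                    "label": c.label.value,
                    "cf_reference_g": c.cf_reference_used,
                    "cf_evidence_g": c.cf_evidence,
                    "rationale": c.rationale,
                }
                for c in self.classifications
            ],
        }

    def to_table(self) -> str:
        lines = [f"{'site':<8}{'label':<16}{'ref CF (g)':>11}{'evidence (g)':>14}"]
        for c in self.classifications:
            ref = "-" if c.cf_reference_used is None else f"{c.cf_reference_used:.1f}"
            ev = "-" if c.cf_evidence is None else f"{c.cf_evidence:.2f}"
            lines.append(f"{c.site_id:<8}{c.label.value:<16}{ref:>11}{ev:>14}")
        lines.append("")
        lines.append(
            "counts: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.counts["total"].items()))
        )
        lines.append("gaps: " + (", ".join(self.gap_sites) if self.gap_sites else "none"))
        return "\n".join(lines)


def survey_report(
    classifications: list[SiteClassification],
    assessments: Optional[list[SiteAssessment]] = None,
    reference: Optional[ReferenceThreshold] = None,
) -> SurveyReport:
    """Assemble counts (in-pattern and out-of-pattern tallied separately —
    whether non-ablated neighbours count toward gap statistics is a
    reporting choice, so the report does not merge them), the gap list and
    the MAP-positive count."""
    if not classifications:
        raise ValueError("need at least one classification")
    in_pattern_ids = None
    if assessments is not None:
        in_pattern_ids = {a.site_id for a in assessments if a.in_lesion_pattern}
    counts = {"total": {}, "in_pattern": {}, "out_of_pattern": {}}
    for c in classifications:
        counts["total"][c.label.value] = counts["total"].get(c.label.value, 0) + 1
        if in_pattern_ids is not None:
            key = "in_pattern" if c.site_id in in_pattern_ids else "out_of_pattern"
            counts[key][c.label.value] = counts[key].get(c.label.value, 0) + 1
    gaps = [c.site_id for c in classifications if c.label is Label.GAP]
    n_pos = sum(1 for c in classifications if c.label in (Label.GAP, Label.CONDUCTIVE))
    return SurveyReport(
        classifications=classifications,
        counts=counts,
        gap_sites=gaps,
        n_map_positive=n_pos,
        reference=reference,
    )
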