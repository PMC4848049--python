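"""Packaged worked-example surveys.

Four read-only site tables transcribe the published epicardial (set1–set3)
and endocardial mitral-isthmus (endocardial_mi) lesion surveys: per site,
whether a MAP was elicited post-ablation, the printed contact force where
one was printed, and otherwise a "supra-reference, exact value unknown"
sentinel. No unprinted number is invented. ``manifest.json`` repeats every
value as double-entry bookkeeping for a cross-check test.
"""

from __future__ import annotations

import json
from importlib import resources

from ..classify import SiteAssessment
from ..errors import UnknownFixtureError

FIXTURE_NAMES = ("set1", "set2", "set3", "endocardial_mi")


def _read(name: str) -> dict:
    with resources.files(__package__).joinpath(f"{name}.json").open() as fh:
        return json.load(fh)


def fixture_names() -> tuple[str, ...]:
    return FIXTURE_NAMES


def load_manifest() -> dict:
    return _read("manifest")


def load_fixture_raw(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return _read(name)


def load_fixture(name: str) -> list[SiteAssessment]:
    """Post-ablation :class:`SiteAssessment` summaries for one worked
    example, ready for ``classify_site`` without raw traces."""
    raw = load_fixture_raw(name)
    out = []
    for s in raw["sites"]:
        out.append(
            SiteAssessment(
                site_id=s["site_id"],
                phase="post_ablation",
                in_lesion_pattern=s["in_pattern"],
                map_present=s["map_present"],
                cf_at_detection=s["cf_at_detection_g"],
                max_cf_applied=s["max_cf_g"],
                supra_reference_force=s["supra_reference"],
            )
        )
    return out
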