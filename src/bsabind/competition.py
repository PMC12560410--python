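"""Site-marker displacement and common-ion effects on the binding constant.

Serum albumin carries two principal drug pockets, Sudlow's site I
(subdomain IIA; probed by indomethacin or warfarin) and site II
(subdomain IIIA; probed by diazepam or ibuprofen).  A ligand's preferred
site is read off a displacement assay: re-measure Ka in the presence of a
saturating site probe and see which probe knocks the constant down.  The
same Ka-ratio machinery reports how added metal ions shift the affinity.
"""

from __future__ import annotations

import enum

from pydantic import BaseModel

from .binding import BindingResult
from .datatypes import AnalysisConfig


class Effect(str, enum.Enum):
    decrease = "decrease"
    increase = "increase"
    unchanged = "unchanged"


class Site(str, enum.Enum):
    site_I = "site_I"   # subdomain IIA
    site_II = "site_II"  # subdomain IIIA
    ambiguous = "ambiguous"


class CompetitionResult(BaseModel):
    """Ka of one condition relative to the blank, with the effect verdict."""

    condition: str
    log10_ka: float
    ka: float
    ka_ratio_to_blank: float
    effect: Effect
    n_sites: float
    r: float


class SiteAssignment(BaseModel):
    site: Site
    displacing_probe: str = ""


def _effect_of(ratio: float, threshold: float) -> Effect:
    # boundary inclusive: |1 - ratio| == threshold is still "unchanged"
    if abs(1.0 - ratio) <= threshold:
        return Effect.unchanged
    return Effect.decrease if ratio < 1.0 else Effect.increase


def compare_conditions(
    blank: BindingResult,
    conditions: list[BindingResult],
    config: AnalysisConfig | None = None,
) -> list[CompetitionResult]:
    """Ka ratio and effect call for each condition against the blank.

    All fits must come from the same temperature.  A condition is
    "unchanged" when its Ka sits within ``significance_ratio_threshold``
    (default +/-25%) of the blank's, "decrease"/"increase" otherwise.
    """
    config = config or AnalysisConfig()
    out = []
    for cond in conditions:
        if cond.temperature_K != blank.temperature_K:
            raise ValueError(
                f"condition {cond.label!r} measured at {cond.temperature_K} K "
                f"but blank at {blank.temperature_K} K"
            )
        ratio = cond.ka / blank.ka
        out.append(
            CompetitionResult(
                condition=cond.label,
                log10_ka=cond.log10_ka,
                ka=cond.ka,
                ka_ratio_to_blank=ratio,
                effect=_effect_of(ratio, config.significance_ratio_threshold),
                n_sites=cond.n_sites,
                r=cond.fit.r,
            )
        )
    return out


def assign_site(
    results: list[CompetitionResult], probe_site_map: dict[str, Site]
) -> SiteAssignment:
    """Read the preferred binding site off the displacement pattern.

    The ligand is assigned to site II when at least one site-II probe
    displaces it (Ka decrease) and no site-I probe does, and vice versa;
    any other pattern (both sites displace, or none does) is ambiguous.
    """
    if not probe_site_map:
        raise ValueError("probe -> site map must not be empty")
    norm_map = {k: Site(v) for k, v in probe_site_map.items()}
    displaced: dict[Site, list[str]] = {Site.site_I: [], Site.site_II: []}
    for res in results:
        site = norm_map.get(res.condition)
        if site is None:
            continue
        if res.effect is Effect.decrease:
            displaced[site].append(res.condition)
    hit_I, hit_II = bool(displaced[Site.site_I]), bool(displaced[Site.site_II])
    if hit_II and not hit_I:
        return SiteAssignment(site=Site.site_II, displacing_probe=displaced[Site.site_II][0])
    if hit_I and not hit_II:
        return SiteAssignment(site=Site.site_I, displacing_probe=displaced[Site.site_I][0])
    return SiteAssignment(site=Site.ambiguous)


def ion_effect(
    blank: BindingResult,
    ion_conditions: list[BindingResult],
    config: AnalysisConfig | None = None,
) -> list[CompetitionResult]:
    """Per-ion affinity change, using the same ratio machinery as the
    site-marker comparison."""
    return compare_conditions(blank, ion_conditions, config)
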