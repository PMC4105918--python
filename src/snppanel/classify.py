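"""The four-criterion decision rule partitioning loci into candidate,
neutral and ambiguous panels.

Flags: (1) directional FST outlier at the 99% envelope, (2) a-priori
precedence of association, (3) robust Bonferroni-significant univariate
environmental regression.  Criterion (4) is the DISTLM ranking: a flagged
locus becomes a candidate only when its top-ranked variable is
environmental with p < 0.05; a flagged locus whose top-ranked variable is
a neutral control (Q or EV) is precluded from candidacy regardless of the
other criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .assoc import AssociationResult
from .distlm import DistlmResult
from .outliers import OutlierResult

PANELS = ("candidate", "neutral", "ambiguous")


@dataclass
class LocusClassification:
    locus: str
    flags: set[str]  # subset of {outlier_99, precedence, linreg}
    distlm_top_variable: str | None
    top_is_control: bool
    panel: str
    climate_factors: str = ""  # P/T/E/D codes of associated variable groups

    def flagged(self) -> bool:
        return bool(self.flags)


def _factor_code(variable: str | None) -> str:
    """Table-style climate-factor code of a DISTLM top variable:
    P precipitation, T temperature, E elevation, D distance/geography."""
    if not variable:
        return ""
    v = variable.lower()
    if v.startswith("precip"):
        return "P"
    if v.startswith(("tmax", "tmin", "temperature")):
        return "T"
    if v.startswith("elev"):
        return "E"
    if v.startswith(("migration", "latitude", "longitude", "geography")):
        return "D"
    return ""


def flag_loci(
    outlier_results: OutlierResult,
    precedence_list: list[str],
    association_results: AssociationResult,
    require_robust: bool = True,
) -> dict[str, set[str]]:
    """Per-locus flag sets from criteria 1–3.

    The regression flag requires significance that survives the
    group-exclusion rerun when one was configured.  Precedence loci no
    longer in the panel (e.g. removed by LD paring) are warned about and
    skipped.
    """
    panel = list(association_results.locus_ids)
    panel_set = set(panel)
    missing = [l for l in precedence_list if l not in panel_set]
    if missing:
        warnings.warn(f"precedence loci absent from panel: {missing}", stacklevel=2)
    flags: dict[str, set[str]] = {l: set() for l in panel}
    for l in outlier_results.directional_loci():
        if l in flags:
            flags[l].add("outlier_99")
    for l in precedence_list:
        if l in flags:
            flags[l].add("precedence")
    for l in association_results.significant_loci(require_robust=require_robust):
        flags[l].add("linreg")
    return flags


def classify_locus(
    flags: set[str],
    distlm_result: DistlmResult | None,
    alpha: float = 0.05,
    linreg_only_failures_ambiguous: bool = False,
) -> str:
    """Panel decision for one locus.

    flagged + environmental top variable (p < alpha)  -> candidate
    flagged via outlier/precedence + control-top/none  -> ambiguous
    flagged via linreg only + control-top/none         -> neutral
      (configurable to ambiguous)
    unflagged                                          -> neutral
    """
    if not flags:
        return "neutral"
    if distlm_result is None:
        raise ValueError("flagged locus is missing its DISTLM result")
    top = distlm_result.top_variable
    if top is not None and not distlm_result.top_is_control:
        return "candidate"
    if flags & {"outlier_99", "precedence"}:
        return "ambiguous"
    return "ambiguous" if linreg_only_failures_ambiguous else "neutral"


def classify_all(
    flags: dict[str, set[str]],
    distlm_results: dict[str, DistlmResult],
    alpha: float = 0.05,
    linreg_only_failures_ambiguous: bool = False,
) -> list[LocusClassification]:
    out = []
    for locus, fl in flags.items():
        dres = distlm_results.get(locus)
        if fl and dres is not None and dres.skipped_reason:
            dres = None
            fl = set()  # unanalyzable response matrix: treat as unflagged
        panel = classify_locus(fl, dres, alpha, linreg_only_failures_ambiguous)
        top = dres.top_variable if dres else None
        is_control = dres.top_is_control if dres else False
        out.append(
            LocusClassification(
                locus=locus,
                flags=fl,
                distlm_top_variable=top,
                top_is_control=is_control,
                panel=panel,
                climate_factors=_factor_code(top) if panel == "candidate" else "",
            )
        )
    return out


@dataclass
class PanelSet:
    neutral: list[str]
    candidate: list[str]
    ambiguous: list[str]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_panels(classifications: list[LocusClassification]) -> PanelSet:
    """Three disjoint locus panels plus a per-locus summary table with
    the climate-factor codes of candidates."""
    panels = {p: [] for p in PANELS}
    recs = []
    for c in classifications:
        panels[c.panel].append(c.locus)
        recs.append(
            (c.locus, ";".join(sorted(c.flags)), c.distlm_top_variable or "",
             c.top_is_control, c.panel, c.climate_factors)
        )
    summary = pd.DataFrame(
        recs,
        columns=["locus", "flags", "distlm_top", "top_is_control", "panel", "climate_factors"],
    )
    return PanelSet(
        neutral=panels["neutral"],
        candidate=panels["candidate"],
        ambiguous=panels["ambiguous"],
        summary=summary,
    )
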