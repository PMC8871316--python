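"""End-to-end report: cross-tabs, agreement, severity shift, recall burden.

``run_report`` executes the full MV-vs-EV comparison on a cohort of nodule
observations and returns a JSON-serialisable dictionary; ``report_from_tables``
does the same starting from already-tabulated cross-classifications (e.g. the
packaged published tables, where per-nodule volumes are unavailable and
distribution summaries are therefore omitted).  ``render_text`` turns either
into the human-readable summary the CLI prints, with percentages at 1 decimal
place and kappa at 2, full precision retained in the machine-readable form.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .agreement import (
    DEFAULT_SCHEME,
    ContingencyTable,
    percent_agreement,
    weighted_kappa,
)
from .cohort import (
    CohortAnalysisResult,
    DominanceRule,
    build_screenee_records,
    compare_recall_burden,
    pn_based_analysis,
    screenee_based_analysis,
    select_dominant,
)
from .volumetry import (
    NoduleObservation,
    OutcomeCategory,
    ScreeningThresholds,
    classify_outcome,
    compute_vdt,
)

__all__ = ["run_report", "report_from_tables", "render_text"]


def _five_number(values: Sequence[float]) -> Optional[dict]:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size == 0:
        return None
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "n": int(vals.size),
        "min": float(vals.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(vals.max()),
    }


def _result_block(res: CohortAnalysisResult, scheme: str) -> dict:
    try:
        kap = weighted_kappa(res.table, scheme)
    except ZeroDivisionError:
        # degenerate marginals (all items in one category): kappa undefined
        kap = None
    return {
        "labels": list(res.table.labels),
        "counts": res.table.counts.tolist(),
        "n_items": res.n_items,
        "n_discordant": res.n_discordant,
        "discordant_fraction": res.discordant_fraction,
        "percent_agreement": percent_agreement(res.table),
        "kappa_scheme": scheme,
        "kappa": kap.kappa if kap else None,
        "observed_weighted_agreement": kap.observed_weighted_agreement if kap else None,
        "expected_weighted_agreement": kap.expected_weighted_agreement if kap else None,
        "upward_shift_fraction": res.upward_shift_fraction,
    }


def run_report(
    observations: Iterable[NoduleObservation],
    thresholds: ScreeningThresholds | None = None,
    scheme: str = DEFAULT_SCHEME,
    rule: DominanceRule = "by_MV",
    horizon_months: float = 36.0,
) -> dict:
    """Full analysis of a cohort observation list.

    Emits, per unit (PN / screenee) and metric (LDCT outcome / VDT
    category): the cross-tab, item and discordance counts, percent
    agreement, weighted kappa, and the severity-shift fraction; plus the
    MV- vs EV-based recall-burden comparison over the horizon and
    five-number summaries of MV, EV and both VDT distributions.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    observations = list(observations)
    cohort = build_screenee_records(observations, thresholds)
    pn = pn_based_analysis(cohort, thresholds)
    sb = screenee_based_analysis(cohort, thresholds, rule=rule)

    # recall burden from per-screenee dominant-nodule categories
    mv_cats, ev_cats = [], []
    dom_rule: DominanceRule = "by_MV" if rule == "worst_category" else rule
    for rec in cohort:
        dom = next(
            o for o in rec.nodules if o.nodule_id == select_dominant(rec, dom_rule)
        )
        mv_cats.append(classify_outcome(dom.measured_volume_mm3, thresholds))
        ev_cats.append(classify_outcome(dom.estimated_volume_mm3, thresholds))
    burden = compare_recall_burden(mv_cats, ev_cats, thresholds, horizon_months)

    mv_vals, ev_vals, mv_vdts, ev_vdts = [], [], [], []
    for rec in cohort:
        for obs in rec.nodules:
            mv_vals.append(obs.measured_volume_mm3)
            ev_vals.append(obs.estimated_volume_mm3)
            follow = rec.followups.get(obs.nodule_id)
            if follow is not None:
                dt = follow.days_from_baseline - obs.days_from_baseline
                mv_vdts.append(
                    compute_vdt(obs.measured_volume_mm3, follow.measured_volume_mm3, dt)
                )
                ev_vdts.append(
                    compute_vdt(obs.estimated_volume_mm3, follow.estimated_volume_mm3, dt)
                )

    return {
        "settings": {
            "scheme": scheme,
            "dominance_rule": rule,
            "horizon_months": horizon_months,
            "thresholds": {
                "neg_max_mm3": thresholds.neg_max_mm3,
                "pos_min_mm3": thresholds.pos_min_mm3,
                "vdt_malignant_max_days": thresholds.vdt_malignant_max_days,
                "vdt_benign_min_days": thresholds.vdt_benign_min_days,
                "min_diameter_mm": thresholds.min_diameter_mm,
                "shrinking_vdt_rule": thresholds.shrinking_vdt_rule,
            },
        },
        "counts": {
            "n_observations": len(observations),
            "n_screenees": len(cohort),
            "n_eligible_nodules": sum(len(r.nodules) for r in cohort),
            "n_followed_up": sum(len(r.followups) for r in cohort),
        },
        "pn_based": {m: _result_block(r, scheme) for m, r in pn.items()},
        "screenee_based": {m: _result_block(r, scheme) for m, r in sb.items()},
        "recall_burden": burden,
        "distributions": {
            "measured_volume_mm3": _five_number(mv_vals),
            "estimated_volume_mm3": _five_number(ev_vals),
            "mv_vdt_days": _five_number(mv_vdts),
            "ev_vdt_days": _five_number(ev_vdts),
        },
    }


def report_from_tables(
    tables: Mapping[str, ContingencyTable],
    thresholds: ScreeningThresholds | None = None,
    scheme: str = DEFAULT_SCHEME,
    horizon_months: float = 36.0,
) -> dict:
    """Analysis starting from the four tabulated cross-classifications.

    Keys: ``pn_ldct``, ``pn_vdt``, ``screenee_ldct``, ``screenee_vdt``.
    The recall-burden comparison uses the screenee LDCT table's row (MV) and
    column (EV) marginals; per-nodule distribution summaries need raw
    volumes and are not available from tables alone.
    """
    if thresholds is None:
        thresholds = ScreeningThresholds()
    blocks = {}
    for key, table in tables.items():
        metric = "ldct_outcome" if key.endswith("ldct") else "vdt_category"
        unit = "PN" if key.startswith("pn") else "screenee"
        res = CohortAnalysisResult.from_table(unit, metric, table)
        blocks[key] = _result_block(res, scheme)
    out = {
        "settings": {"scheme": scheme, "horizon_months": horizon_months},
        "tables": blocks,
    }
    sl = tables.get("screenee_ldct")
    if sl is not None:
        mv_cats = [
            cat for cat, n in zip(OutcomeCategory, sl.row_marginals()) for _ in range(int(n))
        ]
        ev_cats = [
            cat for cat, n in zip(OutcomeCategory, sl.col_marginals()) for _ in range(int(n))
        ]
        out["recall_burden"] = compare_recall_burden(
            mv_cats, ev_cats, thresholds, horizon_months
        )
    return out


def _fmt_block(name: str, block: dict) -> list[str]:
    lines = [f"== {name} =="]
    labels = block["labels"]
    width = max(len(l) for l in labels) + 2
    lines.append(" " * width + "  ".join(f"{l:>14}" for l in labels) + "   (MV rows x EV cols)")
    for lab, row in zip(labels, block["counts"]):
        lines.append(f"{lab:<{width}}" + "  ".join(f"{c:>14}" for c in row))
    kappa_txt = "undefined" if block["kappa"] is None else f"{block['kappa']:.2f}"
    lines.append(
        f"n = {block['n_items']}, discordant = {block['n_discordant']} "
        f"({100 * block['discordant_fraction']:.1f}%), "
        f"agreement = {100 * block['percent_agreement']:.1f}%, "
        f"kappa[{block['kappa_scheme']}] = {kappa_txt}"
    )
    if block["upward_shift_fraction"] is not None:
        lines.append(
            "shift toward shorter follow-up (EV more severe): "
            f"{100 * block['upward_shift_fraction']:.1f}% of discordant"
        )
    return lines


def render_text(report: dict) -> str:
    """Human-readable summary of a report dictionary."""
    lines: list[str] = []
    for section in ("pn_based", "screenee_based", "tables"):
        for metric, block in report.get(section, {}).items():
            lines.extend(_fmt_block(f"{section}:{metric}", block))
            lines.append("")
    burden = report.get("recall_burden")
    if burden:
        lines.append(
            f"Scheduled follow-up LDCTs over {report['settings']['horizon_months']:g} months: "
            f"MV-based = {burden['mv_scans']}, EV-based = {burden['ev_scans']} "
            f"(difference = {burden['difference']})"
        )
    dists = report.get("distributions")
    if dists:
        lines.append("Distribution summaries (median [Q1, Q3]):")
        for name, s in dists.items():
            if s is None:
                lines.append(f"  {name}: no data")
            else:
                lines.append(
                    f"  {name}: {s['median']:.1f} [{s['q1']:.1f}, {s['q3']:.1f}] (n={s['n']})"
                )
    return "\n".join(lines).rstrip() + "\n"
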