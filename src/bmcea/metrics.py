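"""Cost-effectiveness summary measures: ICER, NMB/INMB, plane quadrant."""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CEAResult", "icer", "inmb", "quadrant", "cea_result", "format_table1"]


class MetricsError(ValueError):
    pass


def quadrant(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness plane quadrant from the signs of (ΔE, ΔC)."""
    if delta_effect >= 0:
        return "NE" if delta_cost >= 0 else "SE"
    return "NW" if delta_cost >= 0 else "SW"


def icer(delta_cost: float, delta_effect: float):
    """Incremental cost-effectiveness ratio ΔC/ΔE.

    Returns the ratio in the NE/SW quadrants; the strings ``"dominant"``
    (cheaper and more effective) or ``"dominated"`` (costlier and less
    effective) where a ratio would mislead.  ΔE = 0 raises: the ratio is
    undefined there.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_effect)):
        raise MetricsError("ICER inputs must be finite")
    if delta_effect == 0:
        raise MetricsError("ICER undefined: incremental effect is zero")
    if delta_cost < 0 and delta_effect > 0:
        return "dominant"
    if delta_cost > 0 and delta_effect < 0:
        return "dominated"
    return delta_cost / delta_effect


def inmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Incremental net monetary benefit  λ·ΔE − ΔC  at WTP λ."""
    if wtp < 0:
        raise MetricsError("willingness-to-pay must be non-negative")
    return wtp * delta_effect - delta_cost


@dataclass
class CEAResult:
    """Two-strategy incremental comparison at one WTP threshold."""

    delta_cost: float
    delta_effect: float
    wtp: float
    icer: float | str
    inmb: float
    quadrant: str

    def cost_effective(self) -> bool:
        return self.inmb > 0

    def rounded(self) -> dict:
        """Display precision: integer NT$ (round-half-even), effects to 3 dp."""
        ic = self.icer if isinstance(self.icer, str) else round(self.icer)
        return {
            "delta_cost": round(self.delta_cost),
            "delta_effect": round(self.delta_effect, 3),
            "icer": ic,
            "inmb": round(self.inmb),
            "quadrant": self.quadrant,
            "wtp": round(self.wtp),
        }


def cea_result(delta_cost: float, delta_effect: float, wtp: float) -> CEAResult:
    try:
        ratio = icer(delta_cost, delta_effect)
    except MetricsError:
        ratio = float("nan")
    return CEAResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        wtp=wtp,
        icer=ratio,
        inmb=inmb(delta_cost, delta_effect, wtp),
        quadrant=quadrant(delta_cost, delta_effect),
    )


def format_table1(summary_i: dict, summary_c: dict, wtp: float) -> str:
    """Base-case report: per-arm discounted outcomes and the increments,
    laid out like a standard CEA results table."""
    dc = summary_i["cost_total"] - summary_c["cost_total"]
    dq = summary_i["QALY"] - summary_c["QALY"]
    dl = summary_i["LY"] - summary_c["LY"]
    res_q = cea_result(dc, dq, wtp)
    res_l = cea_result(dc, dl, wtp)
    lines = [
        f"{'':28s}{'intervention':>16s}{'comparator':>16s}",
        f"{'Total cost (NT$)':28s}{summary_i['cost_total']:>16,.0f}{summary_c['cost_total']:>16,.0f}",
        f"{'  medication':28s}{summary_i['cost_medication']:>16,.0f}{summary_c['cost_medication']:>16,.0f}",
        f"{'  other PF cost':28s}{summary_i['cost_pf_other']:>16,.0f}{summary_c['cost_pf_other']:>16,.0f}",
        f"{'  PD-state cost':28s}{summary_i['cost_pd_state']:>16,.0f}{summary_c['cost_pd_state']:>16,.0f}",
        f"{'  terminal care':28s}{summary_i['cost_terminal']:>16,.0f}{summary_c['cost_terminal']:>16,.0f}",
        f"{'QALYs':28s}{summary_i['QALY']:>16.3f}{summary_c['QALY']:>16.3f}",
        f"{'Life-years':28s}{summary_i['LY']:>16.3f}{summary_c['LY']:>16.3f}",
        "",
        f"Incremental cost  : NT${dc:,.0f}",
        f"Incremental QALYs : {dq:.3f}   Incremental LYs: {dl:.3f}",
        f"ICER (per QALY)   : "
        + (res_q.icer if isinstance(res_q.icer, str) else f"NT${res_q.icer:,.0f}"),
        f"ICER (per LY)     : "
        + (res_l.icer if isinstance(res_l.icer, str) else f"NT${res_l.icer:,.0f}"),
        f"INMB (per QALY)   : NT${res_q.inmb:,.0f}   INMB (per LY): NT${res_l.inmb:,.0f}",
        f"WTP threshold     : NT${wtp:,.0f} per QALY",
    ]
    return "\n".join(lines)
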