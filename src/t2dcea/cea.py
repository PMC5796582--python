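"""Cost-effectiveness comparison of two pathway results.

Conventions: the comparison is alt vs ref, with deltas delta = alt - ref.
The ICER delta_cost / delta_effect is defined only in the trade-off
quadrants (alt costs more and gains more, or costs less and loses more);
when one option is both cheaper and more effective the other is dominated
and the ICER is undefined (represented as ``None``, never as a division
artifact).  ICERs are reported at full precision and, for display, rounded
to the nearest $10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import PathwayResult
from .errors import ContractError

ALT_DOMINANT = "alt_dominant"
REF_DOMINANT = "ref_dominant"
TRADEOFF_NE = "tradeoff_NE"
TRADEOFF_SW = "tradeoff_SW"
TIE = "tie"


@dataclass
class CEAResult:
    cost_ref: float
    cost_alt: float
    effect_ref: float
    effect_alt: float
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str

    @property
    def icer_rounded(self) -> float | None:
        """ICER rounded to the nearest $10 (display convention)."""
        if self.icer is None:
            return None
        return round(self.icer / 10.0) * 10.0

    @property
    def cer_ref(self) -> float:
        return self.cost_ref / self.effect_ref

    @property
    def cer_alt(self) -> float:
        return self.cost_alt / self.effect_alt


def cea_from_totals(cost_ref: float, effect_ref: float, cost_alt: float, effect_alt: float) -> CEAResult:
    """Classify dominance and compute the ICER from raw totals."""
    dc = cost_alt - cost_ref
    de = effect_alt - effect_ref
    if dc == 0.0 and de == 0.0:
        dom, icer = TIE, None
    elif dc <= 0.0 and de >= 0.0:
        dom, icer = ALT_DOMINANT, None
    elif dc >= 0.0 and de <= 0.0:
        dom, icer = REF_DOMINANT, None
    else:
        dom = TRADEOFF_NE if de > 0 else TRADEOFF_SW
        icer = dc / de
    return CEAResult(
        cost_ref=cost_ref,
        cost_alt=cost_alt,
        effect_ref=effect_ref,
        effect_alt=effect_alt,
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        dominance=dom,
    )


def compute_cea(ref: PathwayResult, alt: PathwayResult, discounted: bool = True) -> CEAResult:
    """Compare two pathway runs computed under identical settings."""
    if ref.horizon != alt.horizon or ref.discount_rate != alt.discount_rate:
        raise ContractError(
            "pathway results computed under different horizon/discount settings "
            f"({ref.horizon}@{ref.discount_rate} vs {alt.horizon}@{alt.discount_rate})"
        )
    if discounted:
        return cea_from_totals(
            ref.total_cost_discounted, ref.total_ly_discounted,
            alt.total_cost_discounted, alt.total_ly_discounted,
        )
    return cea_from_totals(
        ref.total_cost_undiscounted, ref.total_ly_undiscounted,
        alt.total_cost_undiscounted, alt.total_ly_undiscounted,
    )


def net_monetary_benefit(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """lambda * delta_effect - delta_cost; positive iff the alternative is
    cost-effective at willingness-to-pay ``wtp``."""
    if wtp < 0 or not math.isfinite(wtp):
        raise ContractError(f"willingness-to-pay {wtp} must be finite and >= 0")
    return wtp * delta_effect - delta_cost
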