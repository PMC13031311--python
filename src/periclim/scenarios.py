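"""Back-of-envelope translations of regression coefficients.

Turns per-°C regression coefficients into interpretable magnitudes: percent
of an outcome standard deviation, grams of body weight for a person of
given height (via the BMI definition weight = BMI * height²), and linear
scaling of a 2 °C reference scenario to other warming levels.  All three
operations are linear in the coefficient; confidence-interval endpoints
scale the same way.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


@dataclass
class ScenarioSpec:
    delta_t: float = 2.0        # °C warming scenario
    height_m: float = 1.80      # reference stature for the weight translation

    def __post_init__(self):
        if self.height_m <= 0:
            raise ValueError("height_m must be positive")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (3.145 -> 3.15 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_sd(coef: float, sd: float) -> float:
    """A per-°C coefficient as a percentage of the outcome SD, 2 decimals."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return round_half_up(100.0 * coef / sd, 2)


def weight_change_grams(bmi_coef: float, delta_t: float, height_m: float) -> float:
    """Body-weight change in grams implied by a BMI coefficient (kg/m² per °C)."""
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    return bmi_coef * delta_t * height_m ** 2 * 1000.0


def scale_scenario(effect_at_2c: float, delta_t: float) -> float:
    """Rescale an effect quoted for the 2 °C reference to another warming."""
    return effect_at_2c * delta_t / 2.0


def scenario_table(results: pd.DataFrame, outcome_sds: dict,
                   spec: ScenarioSpec | None = None,
                   window: str = "-5w;+3w") -> pd.DataFrame:
    """Tabulate scenario magnitudes from a tidy linear results table.

    For each continuous outcome in ``results`` (family linear, stratum all,
    given window): the raw coefficient, its %SD per °C, the scenario-scaled
    %SD, and — for BMI — the implied weight change in grams.
    """
    spec = spec or ScenarioSpec()
    sub = results[(results["family"] == "linear")
                  & (results["stratum"] == "all")
                  & (results["window"] == window)]
    rows = []
    for _, r in sub.iterrows():
        sd = outcome_sds.get(r["outcome"])
        if sd is None:
            continue
        pct = percent_of_sd(r["alpha"], sd)
        row = {
            "outcome": r["outcome"],
            "window": window,
            "alpha_per_degc": r["alpha"],
            "pct_sd_per_degc": pct,
            "delta_t": spec.delta_t,
            "pct_sd_at_delta_t": round_half_up(
                scale_scenario(pct * 2.0, spec.delta_t), 2),
            "weight_grams_at_delta_t": (
                round_half_up(weight_change_grams(
                    r["alpha"], spec.delta_t, spec.height_m), 0)
                if r["outcome"] == "bmi" else None
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
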