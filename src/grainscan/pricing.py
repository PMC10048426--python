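"""Adulteration pricing: per-grain price factors for mixed rice samples.

A mixed sample's value is proxied by weighting each variety's market price
p_i with the grain-volume surrogate L_i * l_i^2 (length times width
squared), since grain weight is not observed.  Three factors are compared:

* actual      — weighted by the true per-variety counts N_i,
* predicted   — weighted by the classifier's predicted counts M_i,
* unadulterated — the factor of a pure sample of the majority variety.

All three are computed per grain (the weighted sum divided by the grain
count) so they live on one scale and can be compared directly; a ``total``
flag restores the summed convention.  A relative gap between the predicted
and unadulterated factors beyond a configurable margin flags adulteration.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMixtureError, InvalidParameterError, MissingPriceError

__all__ = [
    "PriceTable",
    "PriceReport",
    "EXAMPLE_PRICES",
    "price_factor",
    "price_factor_unadulterated",
    "adulteration_report",
]


@dataclass(frozen=True)
class VarietyPricing:
    price_per_kg: float
    mean_length: float
    mean_width: float

    @property
    def per_grain_value(self) -> float:
        """p * L * l^2 — price times the volume proxy of one grain."""
        return self.price_per_kg * self.mean_length * self.mean_width**2


class PriceTable:
    """Per-variety price and mean grain dimensions.

    Dimensions may be in pixels or mm as long as they are consistent across
    varieties (the factors are proxies, not currency amounts).
    """

    def __init__(self, entries: Mapping[str, tuple[float, float, float]]):
        self._entries: dict[str, VarietyPricing] = {}
        for name, (price, length, width) in entries.items():
            if price <= 0:
                raise InvalidParameterError(f"{name}: price must be positive")
            if not length >= width > 0:
                raise InvalidParameterError(f"{name}: need L >= l > 0")
            self._entries[name] = VarietyPricing(price, length, width)

    def __getitem__(self, name: str) -> VarietyPricing:
        try:
            return self._entries[name]
        except KeyError:
            raise MissingPriceError(f"no price entry for variety {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def varieties(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceTable":
        df = pd.read_csv(path)
        required = {"variety", "price_per_kg", "mean_length", "mean_width"}
        if not required.issubset(df.columns):
            raise InvalidParameterError(
                f"price table needs columns {sorted(required)}"
            )
        return cls(
            {
                str(r.variety): (float(r.price_per_kg), float(r.mean_length), float(r.mean_width))
                for r in df.itertuples()
            }
        )

    @classmethod
    def from_feature_table(
        cls, table: pd.DataFrame, prices: Mapping[str, float]
    ) -> "PriceTable":
        """Mean length/width per variety estimated from a labeled feature
        table; ``prices`` supplies price per kg."""
        means = table.groupby("variety")[["length", "width"]].mean()
        return cls(
            {
                v: (float(prices[v]), float(means.loc[v, "length"]), float(means.loc[v, "width"]))
                for v in means.index
                if v in prices
            }
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "variety": v,
                "price_per_kg": e.price_per_kg,
                "mean_length": e.mean_length,
                "mean_width": e.mean_width,
            }
            for v, e in self._entries.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")


#: synthetic stand-in market prices (currency/kg) for the eight varieties;
#: ordering reflects the usual premium of basmati over kolam/masuri types
EXAMPLE_PRICES: dict[str, float] = {
    "BM": 120.0,
    "KB": 95.0,
    "TB": 80.0,
    "TKB": 60.0,
    "EK": 55.0,
    "HK": 50.0,
    "WK": 45.0,
    "SM": 65.0,
}


def price_factor(
    counts: Mapping[str, int], prices: PriceTable, *, total: bool = False
) -> float:
    """Sum_i p_i L_i l_i^2 c_i, divided by the grain count unless ``total``.

    Serves both the actual factor (counts = true N_i) and the predicted
    factor (counts = predicted M_i).
    """
    n = sum(counts.values())
    if n == 0:
        raise EmptyMixtureError("mixture has no grains")
    if any(c < 0 for c in counts.values()):
        raise InvalidParameterError("counts must be non-negative")
    acc = sum(prices[v].per_grain_value * c for v, c in counts.items() if c > 0)
    return float(acc if total else acc / n)


def price_factor_unadulterated(
    counts: Mapping[str, int], prices: PriceTable, *, total: bool = False
) -> float:
    """Factor of a pure sample of the majority variety.

    Majority = argmax count; ties break to the higher-priced variety.
    """
    n = sum(counts.values())
    if n == 0:
        raise EmptyMixtureError("mixture has no grains")
    majority = max(
        (v for v, c in counts.items() if c > 0),
        key=lambda v: (counts[v], prices[v].price_per_kg),
    )
    value = prices[majority].per_grain_value
    return float(value * n if total else value)


@dataclass
class PriceReport:
    """Pricing verdict for one mixed sample."""

    predicted_pf: float
    unadulterated_pf: float
    actual_pf: float | None
    price_error_pct: float | None
    adulteration_flag: bool
    detection_rate: float | None
    majority_variety: str
    predicted_counts: dict[str, int]
    actual_counts: dict[str, int] | None

    def to_json(self) -> dict:
        return {
            "predicted_price_factor": self.predicted_pf,
            "unadulterated_price_factor": self.unadulterated_pf,
            "actual_price_factor": self.actual_pf,
            "price_error_pct": self.price_error_pct,
            "adulteration_flag": self.adulteration_flag,
            "detection_rate": self.detection_rate,
            "majority_variety": self.majority_variety,
            "predicted_counts": self.predicted_counts,
            "actual_counts": self.actual_counts,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")


def adulteration_report(
    predictions: Sequence[str],
    prices: PriceTable,
    truth: Sequence[str] | None = None,
    *,
    margin: float = 0.05,
) -> PriceReport:
    """Full pricing verdict from per-grain variety predictions.

    When ground-truth varieties are supplied, the actual factor, the percent
    price error 100*|predicted - actual|/actual and the minority detection
    rate (fraction of minority grains predicted as any non-majority variety)
    are included; otherwise they are reported as unavailable.  The majority
    variety for the unadulterated baseline comes from the truth when
    available, else from the predictions.
    """
    if len(predictions) == 0:
        raise EmptyMixtureError("no predicted grains")
    pred_counts = dict(Counter(predictions))
    predicted_pf = price_factor(pred_counts, prices)

    actual_pf = None
    price_error = None
    detection_rate = None
    actual_counts = None
    if truth is not None:
        if len(truth) != len(predictions):
            raise InvalidParameterError("truth and predictions length mismatch")
        actual_counts = dict(Counter(truth))
        actual_pf = price_factor(actual_counts, prices)
        base_counts = actual_counts
    else:
        base_counts = pred_counts

    majority = max(
        base_counts, key=lambda v: (base_counts[v], prices[v].price_per_kg)
    )
    unadulterated_pf = price_factor_unadulterated(base_counts, prices)

    if truth is not None:
        price_error = 100.0 * abs(predicted_pf - actual_pf) / actual_pf
        minority_idx = [i for i, t in enumerate(truth) if t != majority]
        if minority_idx:
            hits = sum(1 for i in minority_idx if predictions[i] != majority)
            detection_rate = hits / len(minority_idx)

    flag = (
        abs(predicted_pf - unadulterated_pf) / unadulterated_pf > margin
    )
    return PriceReport(
        predicted_pf=predicted_pf,
        unadulterated_pf=unadulterated_pf,
        actual_pf=actual_pf,
        price_error_pct=price_error,
        adulteration_flag=bool(flag),
        detection_rate=detection_rate,
        majority_variety=majority,
        predicted_counts=pred_counts,
        actual_counts=actual_counts,
    )
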