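"""Cross-sample stability comparison.

Three independent monitors of degradation rate are fitted over the same
initial window — relative EOT change (%/min), rugate-peak shift (nm/min)
and the normalized H parameter (1/min) — and samples are ranked from most
to least stable (smallest to largest initial |rate|) under each metric.
The report flags whether all metrics agree, mirroring the experimental
conclusion that spectrometer- and camera-based monitors rank sample
stability consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color import HueSeries, color_rate
from .spectral import DegradationSeries, fit_rate

__all__ = ["StabilityReport", "build_stability_report"]

_METRICS = ("rel_eot_pct_per_min", "rugate_nm_per_min", "h_norm_per_min")


@dataclass
class StabilityReport:
    """Initial-rate estimates and stability rankings across samples."""

    rates: pd.DataFrame          # index: sample; columns: metrics (+window)
    rankings: dict               # metric -> list of sample names
    agreement: bool
    ties: dict                   # metric -> bool
    window: tuple

    def to_text(self) -> str:
        lines = [f"Stability report (initial-rate window "
                 f"{self.window[0]:g}-{self.window[1]:g} min)", ""]
        lines.append(self.rates.to_string(float_format=lambda v: f"{v: .5g}"))
        lines.append("")
        for metric, order in self.rankings.items():
            tie = "  [tie]" if self.ties[metric] else ""
            lines.append(f"{metric}: most stable -> least stable: "
                         + " > ".join(order) + tie)
        if self.rankings:
            lines.append("")
            lines.append(f"metrics agree: {self.agreement}")
        return "\n".join(lines)


def build_stability_report(samples: dict, window: tuple = (0.0, 25.0),
                           rtol: float = 1e-9) -> StabilityReport:
    """Rank samples by initial degradation rate under each metric.

    ``samples`` maps sample name to a ``(DegradationSeries, HueSeries)``
    pair (the hue series may be None for spectra-only runs). Ranking is by
    ascending |slope|; |slopes| within relative tolerance ``rtol`` are tied
    (tied samples keep input order and the tie is flagged). ``agreement``
    is true when every computed metric yields the same ordering.
    """
    if not samples:
        raise ValueError("no samples given")
    rows = {}
    for name, (deg, hue) in samples.items():
        if not isinstance(deg, DegradationSeries):
            raise TypeError(f"sample {name}: expected a DegradationSeries")
        row = {}
        row["rel_eot_pct_per_min"] = fit_rate(deg.times, deg.rel_eot_change,
                                              window).slope
        row["rugate_nm_per_min"] = fit_rate(deg.times, deg.rugate_peak,
                                            window).slope
        if hue is not None:
            if not isinstance(hue, HueSeries):
                raise TypeError(f"sample {name}: expected a HueSeries")
            row["h_norm_per_min"] = color_rate(hue, window).slope
        else:
            row["h_norm_per_min"] = np.nan
        rows[name] = row
    rates = pd.DataFrame.from_dict(rows, orient="index")[list(_METRICS)]

    names = list(samples)
    rankings = {}
    ties = {}
    if len(names) >= 2:
        for metric in _METRICS:
            mags = rates[metric].abs()
            if mags.isna().any():
                continue
            order = sorted(names, key=lambda nm: (mags[nm],
                                                  names.index(nm)))
            rankings[metric] = order
            scale = max(mags.max(), 1e-30)
            ties[metric] = bool(np.any(np.abs(np.diff(mags[order]))
                                       <= rtol * scale))
    orders = list(rankings.values())
    agreement = all(o == orders[0] for o in orders) if orders else True
    return StabilityReport(rates, rankings, agreement, ties, tuple(window))
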