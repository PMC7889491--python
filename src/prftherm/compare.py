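"""Comparison of reconstructed (measured) and simulated heating maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recon import rmse_map

__all__ = ["ComparisonReport", "compare_maps"]


@dataclass
class ComparisonReport:
    """Agreement metrics between a measured and a simulated dT map."""

    rmse_C: float
    max_abs_diff_C: float
    diff_map: np.ndarray
    probe_deviation_C: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": "rmse_C", "value": self.rmse_C},
                {"metric": "max_abs_diff_C", "value": self.max_abs_diff_C}]
        rows += [{"metric": f"probe_deviation_C[{k}]", "value": v}
                 for k, v in self.probe_deviation_C.items()]
        return pd.DataFrame(rows)


def compare_maps(measured: np.ndarray, simulated: np.ndarray,
                 mask: np.ndarray | None = None,
                 probe_values: dict | None = None,
                 probe_rois: dict | None = None) -> ComparisonReport:
    """Masked RMSE and maximum difference, plus probe-ROI deviations.

    ``probe_values``/``probe_rois`` map probe names to fibre-optic
    readings (degC) and boolean ROIs on the measured grid; the reported
    deviation is (measured ROI mean) - (probe reading).
    """
    rmse, diff = rmse_map(measured, simulated, mask)
    m = np.ones(measured.shape, bool) if mask is None else np.asarray(mask, bool)
    report = ComparisonReport(rmse_C=rmse,
                              max_abs_diff_C=float(np.max(np.abs(diff[m]))),
                              diff_map=diff)
    if probe_values:
        for name, value in probe_values.items():
            roi = np.asarray(probe_rois[name], dtype=bool)
            report.probe_deviation_C[name] = \
                float(np.mean(measured[roi])) - float(value)
    return report
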