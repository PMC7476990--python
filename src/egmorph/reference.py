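"""Published reference values for the ex vivo uncoupling comparison.

These are the printed per-feature means/SDs and percent changes from an
intact porcine/human Langendorff study comparing baseline electrograms with
recordings after carbenoxolone-induced gap-junction uncoupling, together
with its stimulus-to-(-dV/dt)max latencies.  They serve as worked-example
inputs (the raw recordings behind them were not deposited): the package's
own ``percent_change`` and amplitude definitions can be checked directly
against the printed cells.

Units: intervals/widths ms, amplitudes mV, gradients mV/ms; latencies ms.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_feature_table",
    "REFERENCE_LATENCY_MS",
    "REFERENCE_SINGLE_BEAT_LATENCIES_MS",
]

#: (feature, bl_mean, bl_sd, cbx_mean, cbx_sd, printed percent change, significant)
_ROWS = [
    ("rs_interval", 182.01, 1093.43, 149.96, 1061.53, -17.61, False),
    ("qr_interval", 68.59, 154.71, 63.21, 164.99, -7.84, False),
    ("qs_interval", 250.60, 1151.87, 213.17, 1159.46, -14.94, False),
    ("egm_duration", 292.98, 1155.80, 265.20, 1163.59, -9.48, False),
    ("q_point", 0.81, 0.96, 0.92, 1.05, 13.86, True),
    ("r_point", 3.13, 7.92, 2.55, 2.12, -18.60, True),
    ("s_point", -3.40, 3.06, -4.74, 2.66, -39.40, True),
    ("endpoint_amplitude", -0.24, 2.02, -0.50, 2.14, -106.85, True),
    ("rs_gradient", -0.31, 1.01, -0.36, 0.33, -17.79, False),
    ("qr_gradient", 0.06, 0.24, 0.06, 0.10, -1.49, False),
    ("s_endpoint_gradient", 0.17, 0.29, 0.26, 1.40, 54.93, True),
    ("fractionation_index", 29.27, 89.76, 83.52, 327.44, 185.30, True),
    ("r_width", 159.59, 613.57, 138.19, 635.67, -13.41, False),
    # the S-width baseline SD is garbled in the published table; recorded as-is
    ("s_width", 133.39, 553.10, 127.01, 127.01, -4.78, False),
    ("rs_ratio", -1.35, 1.81, -0.83, 1.06, 38.58, True),
    ("rs_width_ratio", 1.95, 4.28, 1.97, 8.06, 1.04, False),
    ("rs_width_over_duration", 0.50, 0.21, 0.48, 0.23, -4.30, True),
    ("dvdt_max", 2.17, 7.83, 1.72, 2.01, -20.94, False),
    ("amplitude", 6.53, 9.39, 7.28, 3.21, 11.58, True),
]


def reference_feature_table() -> pd.DataFrame:
    """The published 19-feature BL/CBX comparison as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "feature", "bl_mean", "bl_sd", "cbx_mean", "cbx_sd",
            "pct_change_printed", "significant",
        ],
    )


#: mean +/- SD stimulus-to-(-dV/dt)max latency across all electrodes (ms)
REFERENCE_LATENCY_MS = {"BL": (47.9, 4.1), "CBX": (67.2, 2.7)}

#: single-trace latencies quoted for illustrative beats (ms)
REFERENCE_SINGLE_BEAT_LATENCIES_MS = {
    "porcine_bl": 114.8,
    "porcine_cbx": 164.1,
    "human_bl": 108.6,
}
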