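"""Small assay computations: ΔΔCt qPCR fold-changes and normalized
proteasome activity from luminescence traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DataError(ValueError):
    pass


def ddct_fold_change(
    table: pd.DataFrame,
    housekeeping: str,
    control: str,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Relative quantification by the ΔΔCt method.

    ``table`` has columns ``sample``, ``gene``, ``ct`` and optionally
    ``replicate``.  Per sample, ΔCt = Ct_gene - Ct_housekeeping (replicate
    Cts averaged first by default; with ``per_replicate`` the ΔΔCt is formed
    replicate-wise and then summarized).  ΔΔCt = ΔCt_sample - ΔCt_control and
    fold-change = 2**-ΔΔCt.  The spread column is the fold-change range over
    replicates (range method), NaN without replicates.

    Returns a frame with columns ``sample``, ``gene``, ``ddct``,
    ``fold_change``, ``fold_change_lo``, ``fold_change_hi``.
    """
    req = {"sample", "gene", "ct"}
    if not req.issubset(table.columns):
        raise DataError(f"table must have columns {sorted(req)}")
    if not np.all(np.isfinite(table["ct"])):
        raise DataError("non-finite Ct values")
    genes = [g for g in table["gene"].unique() if g != housekeeping]
    samples = list(table["sample"].unique())
    if control not in samples:
        raise DataError(f"control condition {control!r} not present")

    def mean_ct(sample, gene):
        sub = table[(table["sample"] == sample) & (table["gene"] == gene)]["ct"]
        if sub.empty:
            raise DataError(f"missing Ct for sample {sample!r}, gene {gene!r}")
        return float(sub.mean()), sub.to_numpy(dtype=float)

    rows = []
    for gene in genes:
        dct_ctrl, _ = _dct(table, control, gene, housekeeping, mean_ct)
        for sample in samples:
            dct, spread = _dct(table, sample, gene, housekeeping, mean_ct, per_replicate)
            ddct = dct - dct_ctrl
            fc = 2.0**-ddct
            if spread is not None and len(spread) > 1:
                ddcts = spread - dct_ctrl
                fcs = 2.0**-ddcts
                lo, hi = float(fcs.min()), float(fcs.max())
            else:
                lo = hi = float("nan")
            rows.append(
                {
                    "sample": sample,
                    "gene": gene,
                    "ddct": ddct,
                    "fold_change": fc,
                    "fold_change_lo": lo,
                    "fold_change_hi": hi,
                }
            )
    return pd.DataFrame(rows)


def _dct(table, sample, gene, housekeeping, mean_ct, per_replicate=False):
    g_mean, g_all = mean_ct(sample, gene)
    h_mean, h_all = mean_ct(sample, housekeeping)
    if per_replicate and len(g_all) == len(h_all):
        dcts = g_all - h_all
        return float(dcts.mean()), dcts
    dcts = g_all - h_mean if len(g_all) > 1 else None
    return g_mean - h_mean, dcts


@dataclass
class ProteasomeActivity:
    condition: str
    peak_luminescence: float
    background: float
    growth: float
    activity: float
    mode: str
    flagged: bool  # background exceeded signal


def proteasome_activity(
    traces: pd.DataFrame,
    growth: pd.DataFrame,
    mode: str = "epoxomicin",
) -> pd.DataFrame:
    """Normalized proteasome activity per condition from luminescence traces.

    ``traces`` has columns ``time_min``, ``condition``, ``role``,
    ``luminescence`` with roles "treated" plus a background role:
    "epoxomicin_background" (proteasome-inhibited wells) or "cell_free"
    depending on ``mode``.  ``growth`` has columns ``condition``, ``srb``.

    activity = (peak treated luminescence - peak background) / SRB growth.
    Peak is the maximum over the trace.  Activities <= 0 (background above
    signal) are reported as-is with ``flagged`` set, never clipped.
    """
    role_bg = {"epoxomicin": "epoxomicin_background", "cell_free": "cell_free"}.get(mode)
    if role_bg is None:
        raise ValueError("mode must be 'epoxomicin' or 'cell_free'")
    req = {"time_min", "condition", "role", "luminescence"}
    if not req.issubset(traces.columns):
        raise DataError(f"traces must have columns {sorted(req)}")
    growth_map = dict(zip(growth["condition"], growth["srb"]))
    rows = []
    for cond, sub in traces.groupby("condition"):
        treated = sub[sub["role"] == "treated"]["luminescence"]
        bg = sub[sub["role"] == role_bg]["luminescence"]
        if treated.empty or bg.empty:
            raise DataError(f"condition {cond!r}: missing treated or {role_bg} wells")
        if cond not in growth_map:
            raise DataError(f"condition {cond!r}: no growth (SRB) value")
        g = float(growth_map[cond])
        if g <= 0:
            raise DataError(f"condition {cond!r}: non-positive growth normalizer")
        peak = float(treated.max())
        background = float(bg.max())
        act = (peak - background) / g
        rows.append(
            {
                "condition": cond,
                "peak_luminescence": peak,
                "background": background,
                "growth": g,
                "activity": act,
                "mode": mode,
                "flagged": act <= 0,
            }
        )
    return pd.DataFrame(rows)
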