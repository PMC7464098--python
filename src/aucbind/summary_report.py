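"""Assay summary table: absolute rates, percent-of-control, fold changes.

Mirrors the conventional enzymology summary: one row per reductase variant,
columns for HO activity (turnover, min⁻¹) and the apparent heme-reduction
rate constant (min⁻¹), each with a percent-of-control column relative to the
wild-type reductase row.  Values are kept at full precision internally;
rounding (round-half-even to significant figures) happens only at render
time.  Cells with no measurement are rendered ``ND`` and excluded from all
arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

#: canonical row order of the summary table
CANONICAL_ORDER = (
    "rCPR",
    "147CC514",
    "DTT-treated rCPR",
    "DTT-treated 147CC514",
    "IAM/DTT-treated rCPR",
    "IAM/DTT-treated 147CC514",
    "dTGEE",
)


@dataclass(frozen=True)
class Quantity:
    """A measured value with (optional) standard deviation."""

    value: float
    sd: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValidationError("value must be finite")
        if self.sd is not None and self.sd < 0:
            raise ValidationError("sd must be >= 0")


def percent_of_control(value: Quantity, control: Quantity) -> Quantity:
    """100 · value/control with first-order error propagation.

    Relative variances add in quadrature; the result's SD is None when both
    inputs lack one.
    """
    if control.value <= 0:
        raise ValidationError("control must be > 0")
    pct = 100.0 * value.value / control.value
    rel2 = 0.0
    have_sd = False
    if value.sd is not None and value.value != 0:
        rel2 += (value.sd / value.value) ** 2
        have_sd = True
    if control.sd is not None:
        rel2 += (control.sd / control.value) ** 2
        have_sd = True
    return Quantity(pct, abs(pct) * math.sqrt(rel2) if have_sd else None)


def fold_change(control: float, value: float) -> float:
    """How many fold lower ``value`` is than ``control`` (control/value)."""
    if value <= 0:
        raise ValidationError("value must be > 0")
    return control / value


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (round-half-even)."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{sig}g}")


def format_sig(x: float | None, sig: int) -> str:
    if x is None:
        return "ND"
    return f"{x:.{sig}g}"


@dataclass
class AssaySummary:
    """Machine-readable summary plus rendering helpers."""

    table: pd.DataFrame  # full-precision values; NaN where not determined
    control: str

    def to_dict(self) -> dict:
        out = {}
        for variant, row in self.table.iterrows():
            out[variant] = {
                k: (None if pd.isna(v) else float(v)) for k, v in row.items()
            }
        return out

    def render_markdown(self, sig: int = 3) -> str:
        """Text table in the conventional layout (3 significant figures)."""
        lines = [
            "| Reduction system | HO activity (min⁻¹) | (%) | "
            "Reduction rate constant (min⁻¹) | (%) |",
            "| --- | --- | --- | --- | --- |",
        ]
        for variant, row in self.table.iterrows():
            cells = [variant]
            for col, sdcol in (
                ("ho_activity", "ho_activity_sd"),
                ("ho_activity_pct", "ho_activity_pct_sd"),
                ("rate_constant", "rate_constant_sd"),
                ("rate_constant_pct", "rate_constant_pct_sd"),
            ):
                v = row[col]
                if pd.isna(v):
                    cells.append("ND")
                else:
                    s = format_sig(float(v), sig)
                    sd = row[sdcol]
                    if not pd.isna(sd):
                        s += f" ± {format_sig(float(sd), 2)}"
                    cells.append(s)
            # interleave activity/percent columns in table order
            cells = [cells[0], cells[1], cells[2], cells[3], cells[4]]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


def build_summary(
    assay_results: dict[str, Quantity | None],
    kinetics_results: dict[str, Quantity | None],
    kd_results: dict[str, Quantity | None] | None = None,
    control: str = "rCPR",
) -> AssaySummary:
    """Assemble the summary table from per-variant measurements.

    ``assay_results`` maps variant → HO turnover (min⁻¹), ``kinetics_results``
    maps variant → apparent reduction rate constant (min⁻¹); ``None`` (or a
    missing key) marks an undetermined cell.  Percent columns are relative to
    the ``control`` row, which must carry a value in at least one column.
    Rows are emitted in canonical order regardless of input order; unknown
    variants follow, sorted by name.
    """
    variants = set(assay_results) | set(kinetics_results) | set(kd_results or {})
    if control not in variants:
        raise ValidationError(f"control row {control!r} missing from inputs")
    ordered = [v for v in CANONICAL_ORDER if v in variants]
    ordered += sorted(variants - set(ordered))

    act_ctrl = assay_results.get(control)
    kin_ctrl = kinetics_results.get(control)
    if act_ctrl is None and kin_ctrl is None:
        raise ValidationError(f"control row {control!r} has no measurements")

    rows = {}
    for v in ordered:
        row = dict.fromkeys(
            (
                "ho_activity", "ho_activity_sd",
                "ho_activity_pct", "ho_activity_pct_sd",
                "rate_constant", "rate_constant_sd",
                "rate_constant_pct", "rate_constant_pct_sd",
                "kd_uM", "kd_uM_sd",
            ),
            math.nan,
        )
        act = assay_results.get(v)
        if act is not None:
            row["ho_activity"] = act.value
            row["ho_activity_sd"] = act.sd if act.sd is not None else math.nan
            if v == control:
                row["ho_activity_pct"] = 100.0  # exactly, by definition
            elif act_ctrl is not None:
                pct = percent_of_control(act, act_ctrl)
                row["ho_activity_pct"] = pct.value
                row["ho_activity_pct_sd"] = (
                    pct.sd if pct.sd is not None else math.nan
                )
        kin = kinetics_results.get(v)
        if kin is not None:
            row["rate_constant"] = kin.value
            row["rate_constant_sd"] = kin.sd if kin.sd is not None else math.nan
            if v == control:
                row["rate_constant_pct"] = 100.0
            elif kin_ctrl is not None:
                pct = percent_of_control(kin, kin_ctrl)
                row["rate_constant_pct"] = pct.value
                row["rate_constant_pct_sd"] = (
                    pct.sd if pct.sd is not None else math.nan
                )
        kd = (kd_results or {}).get(v)
        if kd is not None:
            row["kd_uM"] = kd.value
            row["kd_uM_sd"] = kd.sd if kd.sd is not None else math.nan
        rows[v] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    return AssaySummary(table=table, control=control)
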