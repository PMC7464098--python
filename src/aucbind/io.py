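"""Readers and writers for scans, traces, configs and reports.

Scan files are 2-column delimited text (``radius_cm,absorbance``) with
``#`` comment lines; the wavelength travels in a ``# wavelength_nm = ...``
comment.  Trace files are ``time_s,a406,a420`` or ``time_s,a468`` with an
optional ``# enzyme_conc_uM = ...`` comment.  Both readers report malformed
lines with their line number and reject non-monotone radii/times.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import yaml

from .equilibrium_model import RadialProfile, RunConditions, Species
from .errors import ParseError, ValidationError
from .kinetics import SpectroConstants, TimeTrace

_META_RE = re.compile(r"#\s*(\w+)\s*=\s*(\S+)")


def _parse_delimited(path) -> tuple[dict, list[str], list[list[float]], list[int]]:
    """Comments-metadata, header fields, numeric rows and their line numbers."""
    meta: dict[str, float] = {}
    header: list[str] = []
    rows: list[list[float]] = []
    linenos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _META_RE.match(line)
                if m:
                    try:
                        meta[m.group(1)] = float(m.group(2))
                    except ValueError:
                        meta[m.group(1)] = m.group(2)
                continue
            fields = [f.strip() for f in re.split(r"[,\t;]", line)]
            if not header:
                try:
                    rows.append([float(f) for f in fields])
                    linenos.append(lineno)
                    header = [f"col{i}" for i in range(len(fields))]
                except ValueError:
                    header = fields
                continue
            try:
                rows.append([float(f) for f in fields])
                linenos.append(lineno)
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path, lineno) from None
            if len(rows[-1]) != len(rows[0]):
                raise ParseError(
                    f"expected {len(rows[0])} fields, got {len(rows[-1])}",
                    path,
                    lineno,
                )
    if not rows:
        raise ParseError("no data rows", path)
    return meta, header, rows, linenos


def read_scan(path) -> RadialProfile:
    """Read a radial absorbance scan."""
    meta, header, rows, linenos = _parse_delimited(path)
    if len(rows[0]) != 2:
        raise ParseError(f"scan needs 2 columns, found {len(rows[0])}", path)
    data = np.asarray(rows, dtype=float)
    radii, absorb = data[:, 0], data[:, 1]
    bad = np.nonzero(np.diff(radii) <= 0)[0]
    if bad.size:
        raise ParseError(
            f"radii must be strictly increasing (r={radii[bad[0] + 1]:g} after "
            f"r={radii[bad[0]]:g})",
            path,
            linenos[bad[0] + 1],
        )
    wavelength = float(meta.get("wavelength_nm", 0.0))
    if not wavelength:
        for h in header:  # e.g. "absorbance_455nm"
            m = re.search(r"(\d+(?:\.\d+)?)\s*nm", h)
            if m:
                wavelength = float(m.group(1))
    return RadialProfile(radii, absorb, wavelength)


def write_scan(path, profile: RadialProfile) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wavelength_nm = {profile.wavelength:g}\n")
        fh.write("radius_cm,absorbance\n")
        for r, a in zip(profile.radii, profile.absorbances):
            fh.write(f"{r:.6f},{a:.8g}\n")


def read_trace(path) -> TimeTrace:
    """Read an absorbance time trace (406/420 pair or a single 468 channel)."""
    meta, header, rows, linenos = _parse_delimited(path)
    data = np.asarray(rows, dtype=float)
    times = data[:, 0]
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ParseError("times must be strictly increasing", path, linenos[bad[0] + 1])
    channels: dict[float, np.ndarray] = {}
    for j, name in enumerate(header[1:], start=1):
        m = re.search(r"(\d+(?:\.\d+)?)", name)
        if not m:
            raise ParseError(f"cannot infer wavelength from column {name!r}", path)
        channels[float(m.group(1))] = data[:, j]
    if not channels:
        raise ParseError("trace needs at least one absorbance column", path)
    conc = meta.get("enzyme_conc_uM")
    return TimeTrace(
        times=times,
        channels=channels,
        enzyme_conc_uM=float(conc) if conc is not None else None,
        label=Path(path).stem,
    )


def write_trace(path, trace: TimeTrace) -> None:
    wls = sorted(trace.channels)
    with open(path, "w") as fh:
        if trace.enzyme_conc_uM is not None:
            fh.write(f"# enzyme_conc_uM = {trace.enzyme_conc_uM:g}\n")
        fh.write("time_s," + ",".join(f"a{wl:g}" for wl in wls) + "\n")
        for i, t in enumerate(trace.times):
            vals = ",".join(f"{trace.channels[wl][i]:.8g}" for wl in wls)
            fh.write(f"{t:.6g},{vals}\n")


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)

    def iterencode(self, o, _one_shot=False):
        # json rejects inf by default when allow_nan=False; encode as string
        return super().iterencode(_sanitize(o), _one_shot)


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_report(path, payload: dict) -> None:
    """Write a structured report as JSON (numpy-safe, inf → "inf")."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, cls=_JSONEncoder)
        fh.write("\n")


# -- configuration ----------------------------------------------------------


def species_from_config(name: str, block: dict) -> Species:
    """Build a Species from a config block (extinction listed in mM⁻¹cm⁻¹)."""
    try:
        molar_mass = float(block["molar_mass"])
        vbar = float(block["vbar"])
    except KeyError as exc:
        raise ValidationError(f"species {name!r}: missing key {exc}") from None
    extinction = {
        float(wl): float(eps) * 1000.0
        for wl, eps in (block.get("extinction") or {}).items()
    }
    return Species(name, molar_mass, vbar, extinction)


def conditions_from_config(block: dict) -> RunConditions:
    if "temp_K" in block:
        temp = float(block["temp_K"])
    elif "temp_C" in block:
        temp = float(block["temp_C"]) + 273.15
    else:
        raise ValidationError("run block needs temp_C or temp_K")
    window = block.get("window_cm", (6.90, 7.20))
    r0 = block.get("r0_cm")
    if r0 is None:
        r0 = 0.5 * (float(window[0]) + float(window[1]))
    return RunConditions(
        rotor_speed_rpm=float(block["rpm"]),
        temperature_K=temp,
        solvent_density=float(block["density"]),
        path_length_cm=float(block["path_length_cm"]),
        reference_radius_cm=float(r0),
        radial_window_cm=(float(window[0]), float(window[1])),
    )


def constants_from_config(block: dict | None) -> SpectroConstants:
    block = block or {}
    kwargs = {}
    for key in (
        "delta_eps_406",
        "delta_eps_420",
        "eps_bilirubin_468",
        "eps_nadph_340",
        "eps_cpr_454",
        "eps_heme_ho1_406",
    ):
        if key in block:
            kwargs[key] = float(block[key])
    return SpectroConstants(**kwargs)


def load_config(path) -> dict:
    """Load and structurally validate a pipeline/run config file (YAML)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    cfg: dict = {"raw": raw, "path": str(path)}
    cfg["species"] = {
        name: species_from_config(name, block)
        for name, block in (raw.get("species") or {}).items()
    }
    if "run" in raw:
        cfg["conditions"] = conditions_from_config(raw["run"])
    cfg["constants"] = constants_from_config(raw.get("assay_constants"))
    cfg["fit"] = dict(raw.get("fit") or {})
    cfg["pipeline"] = raw.get("pipeline")
    # referential integrity: every experiment must name known species
    for exp in (cfg["pipeline"] or {}).get("sedeq", []):
        for sp in exp.get("species", []):
            if sp not in cfg["species"]:
                raise ValidationError(
                    f"experiment {exp.get('name', '?')!r} references unknown "
                    f"species {sp!r}"
                )
    return cfg
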