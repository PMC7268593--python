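"""Pipeline configuration: a small INI dialect with a fixed, typed schema.

The dialect is line based::

    [section]
    # comment
    key = value

Keys are case-insensitive and may contain spaces (``ignore data``).  Values
are never quoted.  Unknown sections or keys, wrong types and out-of-range
values raise :class:`ConfigError` naming the offending ``section.key``.
Parsing and serialising round-trip losslessly: ``parse(serialize(parse(t)))
== parse(t)``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Any, Callable

__all__ = ["ConfigError", "ConfigDoc", "parse_config", "serialize_config"]


class ConfigError(ValueError):
    """Raised for unknown keys, type errors and out-of-range values."""


# ---------------------------------------------------------------------------
# typed key descriptors
# ---------------------------------------------------------------------------

@dataclass
class Key:
    """One schema entry: parse/format functions plus default and doc."""

    parse: Callable[[str], Any]
    fmt: Callable[[Any], str]
    default: Any
    doc: str
    check: Callable[[Any], bool] | None = None


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in ("true", "yes", "on", "1"):
        return True
    if s in ("false", "no", "off", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_opt_float(s: str):
    s = s.strip()
    if s.lower() in ("", "none", "nan"):
        return None
    return float(s)


def _parse_ignore(s: str) -> tuple[tuple[int, int], ...]:
    """``"9.4, 12.1"`` -> ``((9, 4), (12, 1))``."""
    out = []
    for tok in s.split(","):
        tok = tok.strip()
        if not tok:
            continue
        try:
            img, roi = tok.split(".")
            out.append((int(img), int(roi)))
        except ValueError:
            raise ValueError(f"bad roi identifier {tok!r} (expected image.roi)")
    return tuple(out)


def _fmt_ignore(v) -> str:
    return ", ".join(f"{i}.{j}" for i, j in v)


def _parse_sideband(s: str):
    """``auto`` or ``"kx,ky"`` in rad/px -> "auto" | (kx, ky)."""
    s = s.strip()
    if s.lower() == "auto":
        return "auto"
    kx, ky = (float(t) for t in s.split(","))
    return (kx, ky)


def _fmt_sideband(v) -> str:
    if v == "auto":
        return "auto"
    return f"{v[0]!r},{v[1]!r}"


def _enum(*choices: str) -> Callable[[str], str]:
    def parse(s: str) -> str:
        s = s.strip().lower()
        if s not in choices:
            raise ValueError(f"{s!r} not one of {choices}")
        return s
    return parse


def _parse_coeffs(s: str):
    s = s.strip()
    if s.lower() in ("", "none", "default"):
        return None
    vals = tuple(float(t) for t in s.split(","))
    if len(vals) != 4:
        raise ValueError("expected 4 comma-separated coefficients c_n0,c_n1,c_r0,c_r1")
    return vals


def _ffloat(v) -> str:
    return repr(float(v))  # repr round-trips exactly


def _pos(v) -> bool:
    return v is None or v > 0


F = Key  # local alias for brevity below

SCHEMA: dict[str, dict[str, Key]] = {
    "meta": {
        "wavelength_nm": F(_parse_opt_float, _ffloat, None,
                           "imaging wavelength in vacuum [nm]", _pos),
        "pixel_size_um": F(_parse_opt_float, _ffloat, None,
                           "detector pixel size [um/px]", _pos),
        "medium_index": F(_parse_opt_float, _ffloat, None,
                          "refractive index of the surrounding medium",
                          lambda v: v is None or v >= 1.0),
        "time_interval_s": F(float, _ffloat, 1.0,
                             "time between frames when no timestamp is available [s]",
                             lambda v: v > 0),
    },
    "holo": {
        "filter_name": F(_enum("disk", "smooth disk", "gauss", "square"), str,
                         "smooth disk", "sideband filter shape"),
        "filter_size_rel": F(float, _ffloat, 1 / 3,
                             "filter radius as a fraction of the carrier distance",
                             lambda v: 0 < v <= 1),
        "sideband": F(_parse_sideband, _fmt_sideband, "auto",
                      "carrier position: auto or kx,ky [rad/px]"),
        "invert_phase": F(_parse_bool, str, False,
                          "flip the reconstructed phase sign"),
    },
    "roi": {
        "size_um": F(float, _ffloat, 10.0,
                     "approximate specimen diameter [um]", lambda v: v > 0),
        "size_variation": F(float, _ffloat, 0.5,
                            "allowed relative deviation from size_um",
                            lambda v: 0 < v < 1),
        "pad_border_px": F(int, str, 10, "ROI bounding-box padding [px]",
                           lambda v: v >= 0),
        "threshold": F(lambda s: s if s.strip().lower() in ("otsu", "dm-nuclei")
                       else float(s),
                       lambda v: v if isinstance(v, str) else _ffloat(v),
                       "otsu", "segmentation threshold: otsu | dm-nuclei | float"),
        "ignore data": F(_parse_ignore, _fmt_ignore, (),
                         "comma list of image.roi identifiers to exclude"),
    },
    "bg.sensor": {
        "profile": F(_enum("offset", "tilt", "poly2o", "image"), str, "tilt",
                     "background model for whole-sensor correction"),
        "border_px": F(_parse_opt_float, lambda v: str(int(v)), 5,
                       "frame border width used as background [px]",
                       lambda v: v is None or v >= 0),
        "binary_threshold": F(_parse_opt_float, _ffloat, None,
                              "pixels with phase below this value are background"),
        "offset_mode": F(_enum("mean", "median"), str, "mean",
                         "statistic for the offset profile"),
    },
    "bg.roi": {
        "profile": F(_enum("offset", "tilt", "poly2o", "image"), str, "poly2o",
                     "background model for per-ROI correction"),
        "border_px": F(_parse_opt_float, lambda v: str(int(v)), None,
                       "frame border width [px]; unset = 10% of ROI size",
                       lambda v: v is None or v >= 0),
        "binary_threshold": F(_parse_opt_float, _ffloat, None,
                              "pixels with phase below this value are background"),
        "offset_mode": F(_enum("mean", "median"), str, "mean",
                         "statistic for the offset profile"),
    },
    "sphere": {
        "method": F(_enum("edge", "image"), str, "image",
                    "edge: contour estimate only; image: 2-D phase fit"),
        "model": F(_enum("projection", "rytov", "rytov-sc"), str, "projection",
                   "forward model for the sphere phase"),
        "refraction_increment_ml_g": F(float, _ffloat, 0.18,
                                       "refraction increment alpha [mL/g]",
                                       lambda v: v > 0),
        "max_evals": F(int, str, 250,
                       "model evaluations allowed per free parameter",
                       lambda v: v > 0),
        "tol": F(float, _ffloat, 1e-9,
                 "relative cost-improvement termination tolerance",
                 lambda v: v > 0),
        "rytov_sc_coeffs": F(_parse_coeffs,
                             lambda v: "default" if v is None else
                             ",".join(repr(float(c)) for c in v),
                             None,
                             "override c_n0,c_n1,c_r0,c_r1 (default: calibrated)"),
    },
    "output": {
        "fit_tif": F(_parse_bool, str, True, "write per-ROI fit visualisation TIF"),
        "hdf5": F(_parse_bool, str, True, "write sensor_data.h5 store"),
    },
}

_SECTION_ORDER = ["meta", "holo", "roi", "bg.sensor", "bg.roi", "sphere", "output"]


@dataclass
class ConfigDoc:
    """Typed configuration document with schema-validated sections."""

    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self):
        for sec in _SECTION_ORDER:
            self.sections.setdefault(sec, {})
            for key, spec in SCHEMA[sec].items():
                self.sections[sec].setdefault(key, copy.copy(spec.default))

    def __getitem__(self, sec: str) -> dict[str, Any]:
        return self.sections[sec]

    def get(self, sec: str, key: str) -> Any:
        return self.sections[sec][key]

    def set(self, sec: str, key: str, value) -> None:
        """Set a value, accepting either typed values or raw strings."""
        sec = sec.strip().lower()
        key = key.strip().lower()
        if sec == "bg":
            raise ConfigError(
                "section [bg] is ambiguous: use [bg.sensor] or [bg.roi]")
        if sec not in SCHEMA:
            raise ConfigError(f"unknown section [{sec}]")
        if key not in SCHEMA[sec]:
            raise ConfigError(f"unknown key {sec}.{key}")
        spec = SCHEMA[sec][key]
        if isinstance(value, str):
            try:
                value = spec.parse(value)
            except ValueError as e:
                raise ConfigError(f"bad value for {sec}.{key}: {e}") from None
        if spec.check is not None and not spec.check(value):
            raise ConfigError(f"value out of range for {sec}.{key}: {value!r}")
        if isinstance(value, float) and not math.isfinite(value):
            raise ConfigError(f"non-finite value for {sec}.{key}")
        self.sections[sec][key] = value

    def copy(self) -> "ConfigDoc":
        return ConfigDoc(copy.deepcopy(self.sections))

    def __eq__(self, other) -> bool:
        return isinstance(other, ConfigDoc) and self.sections == other.sections

    # convenience accessors -------------------------------------------------
    def require_meta(self) -> None:
        """Raise if any of the three physical metadata values is unset."""
        missing = [f"meta.{k}" for k in
                   ("wavelength_nm", "pixel_size_um", "medium_index")
                   if self.sections["meta"][k] is None]
        if missing:
            raise ConfigError("missing required configuration: "
                              + ", ".join(missing))


def parse_config(text: str) -> ConfigDoc:
    """Parse INI-dialect ``text`` into a :class:`ConfigDoc`.

    Missing keys are filled with the documented defaults; ``#`` starts a
    comment; keys are case-insensitive and may contain spaces.
    """
    doc = ConfigDoc()
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section == "bg":
                raise ConfigError(
                    "section [bg] is ambiguous: use [bg.sensor] or [bg.roi]")
            if section not in SCHEMA:
                raise ConfigError(f"unknown section [{section}] (line {lineno})")
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        if section is None:
            raise ConfigError(f"line {lineno}: key outside any [section]")
        key, value = (t.strip() for t in line.split("=", 1))
        doc.set(section, key, value)
    return doc


def serialize_config(doc: ConfigDoc) -> str:
    """Serialize to a complete, commented template (inverse of parse)."""
    lines = []
    for sec in _SECTION_ORDER:
        lines.append(f"[{sec}]")
        for key, spec in SCHEMA[sec].items():
            value = doc.sections[sec][key]
            comment = f"  # {spec.doc}"
            if value is None:
                lines.append(f"# {key} = (unset){comment}")
            else:
                lines.append(f"{key} = {spec.fmt(value)}{comment}")
        lines.append("")
    return "\n".join(lines)
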