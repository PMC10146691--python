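"""Configuration parsing and file I/O contracts.

Interface series travel as CSV with header ``time_s,alpha_b`` plus an
optional ``phase`` column (``on``/``off``); results are JSON carrying every
field of the viscoelastic result plus provenance (config hash, package
version). Run configuration is YAML or JSON, schema-validated with
pydantic; all field names carry their units. Unknown keys warn rather than
fail, so configs written for newer versions degrade gracefully.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .calibration import CorrectionFactorModel, builtin_cf_model
from .circuit import ChannelGeometry, FlowProgram, InterfaceSeries
from .errors import ConfigError, ParseError
from .inference import AnalysisSetup, ViscoelasticResult

__all__ = [
    "RunConfig",
    "load_config",
    "read_series",
    "write_series",
    "write_result",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="allow")


class GeometryConfig(_StrictModel):
    l1_um: float = Field(7500.0, gt=0)
    l2_um: float = Field(4800.0, gt=0)
    w_um: float = Field(250.0, gt=0)
    h_um: float = Field(20.0, gt=0)
    L_in_mm: float = Field(300.0, gt=0)
    L_out_mm: float = Field(300.0, gt=0)

    def build(self) -> ChannelGeometry:
        return ChannelGeometry(
            l1=self.l1_um, l2=self.l2_um, w=self.w_um, h=self.h_um,
            L_in=self.L_in_mm, L_out=self.L_out_mm,
        )


class FluidsConfig(_StrictModel):
    mu_r_mPas: float = Field(1.0, gt=0)
    mu_b_mPas: float | None = Field(None, gt=0)


class ProgramConfig(_StrictModel):
    Q0_mL_h: float = Field(1.0, gt=0)
    Qr_mL_h: float = Field(1.0, gt=0)
    T_s: float = Field(240.0, gt=0)
    on_fraction: float = Field(0.5, gt=0, lt=1)
    cycles: int = Field(1, ge=1)
    dt_s: float = Field(0.5, gt=0)

    def build(self) -> FlowProgram:
        return FlowProgram(
            Q0_mL_h=self.Q0_mL_h, Qr_mL_h=self.Qr_mL_h, T_s=self.T_s,
            on_fraction=self.on_fraction, n_cycles=self.cycles,
            dt_s=self.dt_s,
        )


class CFConfig(_StrictModel):
    """Correction-factor selection: stock depth or explicit coefficients."""

    depth_um: float | None = None
    coefficients: list[float] | None = None
    valid_range: tuple[float, float] = (0.1, 0.9)
    cf0: float | None = None

    def build(self, default_depth: float) -> CorrectionFactorModel:
        if self.coefficients is not None:
            model = CorrectionFactorModel(
                coefficients=tuple(self.coefficients),
                depth=self.depth_um,
                valid_range=self.valid_range,
                cf0=self.cf0,
            )
            return model
        depth = self.depth_um if self.depth_um is not None else default_depth
        return builtin_cf_model(depth)


class FitConfig(_StrictModel):
    n_steady: int = Field(50, ge=1)
    settle_s: float = Field(70.0, ge=0)


class ImagingConfig(_StrictModel):
    pixel_pitch_um: float = Field(1.67, gt=0)
    roi_um: tuple[float, float] = (250.0, 330.0)
    blood_dark: bool = True


class RunConfig(_StrictModel):
    """Validated run configuration with protocol defaults."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    fluids: FluidsConfig = Field(default_factory=FluidsConfig)
    program: ProgramConfig = Field(default_factory=ProgramConfig)
    cf: CFConfig = Field(default_factory=CFConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)

    def analysis_setup(self) -> AnalysisSetup:
        geom = self.geometry.build()
        return AnalysisSetup(
            geometry=geom,
            mu_r=self.fluids.mu_r_mPas,
            cf_model=self.cf.build(default_depth=geom.h),
            program=self.program.build(),
            n_steady=self.fit.n_steady,
            settle_s=self.fit.settle_s,
        )

    def digest(self) -> str:
        """Stable hash of the validated config, for provenance."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_KNOWN_TOP_KEYS = {"geometry", "fluids", "program", "cf", "fit", "imaging"}
# convenience shorthand: a bare top-level `h` selects geometry depth (and
# with it the stock CF model)
_SHORTHAND = {"h": ("geometry", "h_um"), "h_um": ("geometry", "h_um")}


def _warn_unknown(prefix: str, model: BaseModel) -> None:
    extra = getattr(model, "model_extra", None) or {}
    for key in extra:
        warnings.warn(
            f"unknown config key '{prefix}{key}' ignored", stacklevel=3
        )
    for name in type(model).model_fields:
        value = getattr(model, name)
        if isinstance(value, BaseModel):
            _warn_unknown(f"{prefix}{name}.", value)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Missing sections take the stock protocol defaults (7500/4800/250 µm
    geometry, 1 mL/h flows, 240 s period, 0.5 s sampling). Unknown keys
    warn; schema violations raise :class:`ConfigError` itemizing every
    offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    for short, (section, field_name) in _SHORTHAND.items():
        if short in data:
            data.setdefault(section, {})[field_name] = data.pop(short)
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        items = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {items}") from exc
    _warn_unknown("", cfg)
    return cfg


def write_series(
    series: InterfaceSeries, path: str | Path, phase: bool = True
) -> None:
    """Write a series as ``time_s,alpha_b[,phase]`` CSV at full precision."""
    df = pd.DataFrame({"time_s": series.times, "alpha_b": series.alpha})
    if phase and series.program is not None:
        df["phase"] = np.where(series.program.is_on(series.times), "on", "off")
    df.to_csv(path, index=False, float_format="%.17g")


def read_series(
    path: str | Path, program: FlowProgram | None = None
) -> InterfaceSeries:
    """Read an interface series CSV; lossless inverse of
    :func:`write_series`.

    Malformed rows and non-monotone time stamps raise :class:`ParseError`
    carrying the offending line number (1-based, header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"time_s", "alpha_b"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: header must contain {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    for col in ("time_s", "alpha_b"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric {col} at line {bad[0] + 2}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    a = df["alpha_b"].to_numpy(dtype=float)
    if t.size > 1:
        nonmono = np.nonzero(np.diff(t) <= 0)[0]
        if nonmono.size:
            raise ParseError(
                f"{path}: time_s not strictly increasing at line "
                f"{nonmono[0] + 3}"
            )
    bad_a = np.nonzero((a <= 0) | (a >= 1))[0]
    if bad_a.size:
        raise ParseError(
            f"{path}: alpha_b outside (0, 1) at line {bad_a[0] + 2}"
        )
    return InterfaceSeries(t, a, program=program)


def write_result(
    result: ViscoelasticResult,
    path: str | Path,
    config: RunConfig | None = None,
) -> None:
    """Serialize a result (plus provenance) as JSON at full precision."""
    payload = result.to_dict()
    payload["provenance"] = {
        "software": "coflow",
        "version": __version__,
        "config_sha256_16": config.digest() if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
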