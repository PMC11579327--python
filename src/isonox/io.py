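"""Table readers/writers, packaged fixtures and run configuration.

CSV dialect: comma-separated UTF-8 with a mandatory header row, "."
decimal separator, ISO-8601 dates, empty cell = missing. δ values are
stored as plain decimals. Lines starting with ``#`` are provenance
comments and are skipped on read; every file isonox writes carries such
a header (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .core import EmissionInventory, IsotopeSample, SourceSignature
from .errors import ConfigurationError, ParseError

SAMPLE_COLUMNS = [
    "site",
    "period_start",
    "period_end",
    "delta_no2",
    "delta_tno3",
    "delta_nox",
    "analytic_sd",
]

_RESERVED_INVENTORY_ROWS = ("reported_total", "total")


def _data_path(name: str) -> Path:
    return Path(resources.files("isonox").joinpath("data", name))


# --------------------------------------------------------------------------
# readers


def read_samples(path) -> pd.DataFrame:
    """Read a sample table, validating each row as an IsotopeSample.

    Returns a DataFrame with parsed dates and float δ columns (NaN =
    missing); row numbers in error messages are 1-based data rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError("empty sample file", path=path) from None
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"missing column(s) {missing_cols}", path=path)
    if df.empty:
        raise ParseError("sample file has a header but no rows", path=path)
    for col in ("period_start", "period_end"):
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
        except (ValueError, TypeError) as exc:
            raise ParseError(f"unparseable ISO-8601 date: {exc}", path=path, column=col)
    dup = df.duplicated(subset=["site", "period_start"])
    if dup.any():
        raise ParseError(
            f"duplicate (site, period) rows: {df.loc[dup, ['site', 'period_start']].to_dict('records')}",
            path=path,
        )
    for i, row in df.iterrows():
        try:
            IsotopeSample(
                site=str(row["site"]),
                period_start=row["period_start"],
                period_end=row["period_end"],
                delta_no2=float(row["delta_no2"]),
                delta_tno3=_opt(row["delta_tno3"]),
                delta_nox=_opt(row["delta_nox"]),
                analytic_sd=float(row["analytic_sd"]),
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(str(exc), path=path, row=i + 1) from None
    return df


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)


def read_signatures(path) -> dict[str, SourceSignature]:
    """Read a JSON source-signature library into a source-keyed map."""
    path = Path(path)
    try:
        entries = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path=path) from None
    if not isinstance(entries, list) or not entries:
        raise ParseError("signature library must be a non-empty JSON array", path=path)
    out: dict[str, SourceSignature] = {}
    for i, e in enumerate(entries):
        try:
            sig = SourceSignature(
                source=e["source"],
                mean_delta=float(e["mean_delta"]),
                sd_delta=float(e["sd_delta"]),
                range_low=_opt(e.get("range_low")),
                range_high=_opt(e.get("range_high")),
                provenance=e.get("provenance", ""),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"bad signature entry: {exc}", path=path, row=i) from None
        if sig.source in out:
            raise ParseError(f"duplicate source {sig.source!r}", path=path, row=i)
        out[sig.source] = sig
    return out


def read_inventories(path) -> dict[str, EmissionInventory]:
    """Read a long-format inventory CSV into per-region inventories.

    Rows with source ``reported_total`` carry the provider's printed
    total rather than a component.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ParseError("empty inventory file", path=path) from None
    required = {"region", "year", "source", "rate_tons_per_day"}
    if not required.issubset(df.columns):
        raise ParseError(f"missing column(s) {sorted(required - set(df.columns))}", path=path)
    out: dict[str, EmissionInventory] = {}
    for region, grp in df.groupby("region", sort=False):
        totals = grp[grp["source"].isin(_RESERVED_INVENTORY_ROWS)]
        comps = grp[~grp["source"].isin(_RESERVED_INVENTORY_ROWS)]
        if comps["source"].duplicated().any():
            raise ParseError(f"duplicate source rows for region {region!r}", path=path)
        reported = float(totals["rate_tons_per_day"].iloc[0]) if len(totals) else None
        try:
            out[str(region)] = EmissionInventory(
                region=str(region),
                rates=dict(
                    zip(comps["source"], comps["rate_tons_per_day"].astype(float))
                ),
                year=int(grp["year"].iloc[0]),
                reported_total=reported,
            )
        except ValueError as exc:
            raise ParseError(str(exc), path=path) from None
    if not out:
        raise ParseError("inventory file has no regions", path=path)
    return out


def read_inventory(path, region: str | None = None) -> EmissionInventory:
    """Read one region's inventory (the only region when unambiguous)."""
    invs = read_inventories(path)
    if region is None:
        if len(invs) != 1:
            raise ConfigurationError(
                f"inventory file has regions {sorted(invs)}; specify one"
            )
        return next(iter(invs.values()))
    if region not in invs:
        raise ConfigurationError(f"region {region!r} not in inventory ({sorted(invs)})")
    return invs[region]


# --------------------------------------------------------------------------
# writers


def write_table(df: pd.DataFrame, path, seed: int | None = None, config_hash: str = "") -> None:
    """Write a CSV with the provenance header comment.

    Floats are serialized at 6 significant digits; display rounding
    beyond that belongs to the reporting layer.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# isonox {__version__}"
    if config_hash:
        header += f" | config={config_hash}"
    if seed is not None:
        header += f" | seed={seed}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def config_digest(obj: Any) -> str:
    """Short stable hash of a (JSON-serializable) configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# --------------------------------------------------------------------------
# packaged fixtures


def load_fixture_samples() -> pd.DataFrame:
    """The packaged SSAB field campaign sample table (19 site-months)."""
    return read_samples(_data_path("field_samples_ssab.csv"))


def load_fixture_signatures() -> dict[str, SourceSignature]:
    """The packaged literature δ¹⁵N-NOx source-signature library."""
    return read_signatures(_data_path("source_signatures.json"))


def load_fixture_inventories() -> dict[str, EmissionInventory]:
    """The packaged 2022 CEPAM inventories (imperial, coachella, ssab)."""
    return read_inventories(_data_path("cepam_inventory_2022.csv"))


def load_study_config() -> dict:
    """The packaged study configuration (a priori overrides, δ_s,
    site→region mapping, conversion constants)."""
    return yaml.safe_load(_data_path("ssab_study.yaml").read_text())


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Parsed user run configuration (YAML, JSON accepted)."""

    samples: Path | None = None
    signatures: Path | None = None
    inventory: Path | None = None
    region: str | None = None
    delta_soil: float = -33.2
    apriori_override: float | None = None
    aggregate_mode: str = "mean_of_monthly"
    truncate_negative: bool = True
    fractionation: dict = field(default_factory=dict)
    conversion: dict = field(default_factory=dict)
    out_dir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"run config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s) {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(raw)
        for key in ("samples", "signatures", "inventory", "out_dir"):
            if key in kwargs and kwargs[key] is not None:
                p = Path(kwargs[key])
                if not p.is_absolute():
                    p = path.parent / p
                kwargs[key] = p
        cfg = cls(**kwargs, raw=raw)
        if not isinstance(cfg.seed, int):
            raise ConfigurationError("seed must be an integer")
        for key in ("samples", "signatures", "inventory"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{key} path {p} does not exist")
        return cfg

    @property
    def digest(self) -> str:
        return config_digest(self.raw)
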