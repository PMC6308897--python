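"""Embedded database of published allometric regression parameters.

The package ships the full set of fitted coefficients for the eight model
families (LWTR, LWT, LWR, LW, LTR, LT, LR, L) relating log10 live body mass
(mg) to log10 body length (mm), optionally log10 maximum body width (mm),
with taxon- and/or region-specific intercepts and slopes, together with
per-taxon/region sampling metadata (sample sizes and the length/mass ranges
over which each equation was estimated). Coefficients are stored exactly as
published (three decimal places) and are never re-derived.

Users may substitute their own parameter file in the same CSV dialect
(header ``model_id,taxon,region,intercept,slope_length,slope_width,
sig_intercept,sig_length,sig_width``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import IntegrityError, ParameterLookupError, UsageError, ValidationError
from .records import (
    MODEL_IDS,
    MODEL_PREFERENCE,
    REGION_MODELS,
    REGIONS,
    TAXON_MODELS,
    WIDTH_MODELS,
    normalize_name,
)

DATABASE_VERSION = "builtin-1.0"

_PARAMS_HEADER = [
    "model_id", "taxon", "region", "intercept", "slope_length", "slope_width",
    "sig_intercept", "sig_length", "sig_width",
]
_META_HEADER = [
    "taxon", "region", "n_individuals", "n_families",
    "length_min", "length_max", "mass_min", "mass_max",
]

#: Row counts per model family expected of the builtin database.
_EXPECTED_COUNTS = {
    "LWTR": 32, "LWT": 19, "LWR": 2, "LW": 1,
    "LTR": 32, "LT": 19, "LR": 2, "L": 1,
}

_SIG_LEVELS = ("", "*", "**", "***")


@dataclass(frozen=True)
class ParameterSet:
    """One fitted regression equation.

    ``intercept`` is log10 mass (mg) at L = W = 1 mm; the slopes are the
    allometric exponents for length and width on the log10 scale.
    Significance flags (``***``, ``**``, ``*`` or ``""``) are metadata only:
    non-significant coefficients are still used verbatim in prediction.
    """

    model_id: str
    intercept: float
    slope_length: float
    slope_width: float | None = None
    taxon: str | None = None
    region: str | None = None
    sig_intercept: str = ""
    sig_length: str = ""
    sig_width: str = ""

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValidationError(f"unknown model_id {self.model_id!r}")
        if (self.slope_width is not None) != self.uses_width:
            raise ValidationError(
                f"{self.model_id}: slope_width must be present iff the model uses width"
            )
        if (self.taxon is not None) != self.uses_taxon:
            raise ValidationError(
                f"{self.model_id}: taxon must be present iff the model is taxon-specific"
            )
        if (self.region is not None) != self.uses_region:
            raise ValidationError(
                f"{self.model_id}: region must be present iff the model is region-specific"
            )
        if self.region is not None and normalize_name(self.region) not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        for flag in (self.sig_intercept, self.sig_length, self.sig_width):
            if flag not in _SIG_LEVELS:
                raise ValidationError(f"bad significance flag {flag!r}")

    @property
    def uses_width(self) -> bool:
        return self.model_id in WIDTH_MODELS

    @property
    def uses_taxon(self) -> bool:
        return self.model_id in TAXON_MODELS

    @property
    def uses_region(self) -> bool:
        return self.model_id in REGION_MODELS

    @property
    def has_nonsignificant_coefficient(self) -> bool:
        """True if any coefficient the equation uses carries no significance star."""
        flags = [self.sig_intercept, self.sig_length]
        if self.uses_width:
            flags.append(self.sig_width)
        return any(f == "" for f in flags)

    @property
    def key(self) -> tuple[str, str | None, str | None]:
        return (self.model_id, normalize_name(self.taxon), normalize_name(self.region))


@dataclass(frozen=True)
class TaxonRegionMetadata:
    """Sampling metadata for one taxon x region combination.

    The length/mass ranges delimit the domain over which that combination's
    regression parameters were estimated; predictions outside the length
    range are extrapolations.
    """

    taxon: str
    region: str
    n_individuals: int
    n_families: int
    length_range: tuple[float, float]
    mass_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be >= 1")
        for lo, hi in (self.length_range, self.mass_range):
            if not (0 < lo <= hi):
                raise ValidationError(f"range must satisfy 0 < min <= max, got ({lo}, {hi})")


def _fmt(x: float | None, nd: int) -> str:
    return "" if x is None else f"{x:.{nd}f}"


class ParameterDatabase:
    """Queryable collection of :class:`ParameterSet` and sampling metadata."""

    def __init__(
        self,
        parameters: list[ParameterSet],
        metadata: list[TaxonRegionMetadata] = (),
        version: str = "user",
    ):
        self.version = version
        self._params: dict[tuple, ParameterSet] = {}
        for p in parameters:
            if p.key in self._params:
                raise ValidationError(f"duplicate parameter set for {p.key}")
            self._params[p.key] = p
        self._meta: dict[tuple, TaxonRegionMetadata] = {}
        for m in metadata:
            key = (normalize_name(m.taxon), normalize_name(m.region))
            if key in self._meta:
                raise ValidationError(f"duplicate metadata for {key}")
            self._meta[key] = m

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        parameters_path: str | Path,
        metadata_path: str | Path | None = None,
        version: str | None = None,
    ) -> "ParameterDatabase":
        """Load a database from CSV files in the package's parameter dialect."""
        params = _read_parameter_csv(Path(parameters_path))
        meta: list[TaxonRegionMetadata] = []
        if metadata_path is not None:
            meta = _read_metadata_csv(Path(metadata_path))
        return cls(params, meta, version=version or str(parameters_path))

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._params)

    def __iter__(self):
        return iter(self._params.values())

    @property
    def parameters(self) -> list[ParameterSet]:
        return list(self._params.values())

    @property
    def metadata(self) -> list[TaxonRegionMetadata]:
        return list(self._meta.values())

    @property
    def taxa(self) -> set[str]:
        """Distinct taxon names appearing anywhere in the database."""
        return {p.taxon for p in self._params.values() if p.taxon is not None}

    def model_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self._params.values():
            counts[p.model_id] = counts.get(p.model_id, 0) + 1
        return counts

    def has_entry(self, model_id: str, taxon: str | None = None, region: str | None = None) -> bool:
        return (model_id, normalize_name(taxon), normalize_name(region)) in self._params

    def lookup(
        self, model_id: str, taxon: str | None = None, region: str | None = None
    ) -> ParameterSet:
        """Return the unique parameter set for a model family (and taxon/region).

        Raises
        ------
        UsageError
            If taxon/region are supplied or omitted contrary to what the
            model family requires.
        ParameterLookupError
            If the combination was never sampled; the error names the most
            informative model that is applicable instead.
        """
        if model_id not in MODEL_IDS:
            raise UsageError(f"unknown model_id {model_id!r}")
        needs_taxon = model_id in TAXON_MODELS
        needs_region = model_id in REGION_MODELS
        if needs_taxon != (taxon is not None):
            raise UsageError(
                f"model {model_id} {'requires' if needs_taxon else 'does not take'} a taxon"
            )
        if needs_region != (region is not None):
            raise UsageError(
                f"model {model_id} {'requires' if needs_region else 'does not take'} a region"
            )
        key = (model_id, normalize_name(taxon), normalize_name(region))
        try:
            return self._params[key]
        except KeyError:
            fallback = self.nearest_fallback(model_id, taxon, region)
            raise ParameterLookupError(
                f"no {model_id} parameters for taxon={taxon!r}, region={region!r}",
                fallback=fallback,
            ) from None

    def nearest_fallback(
        self, model_id: str, taxon: str | None, region: str | None
    ) -> str | None:
        """Most informative model after ``model_id`` with an entry for this record."""
        start = MODEL_PREFERENCE.index(model_id)
        has_width = model_id in WIDTH_MODELS  # width was evidently available
        for candidate in MODEL_PREFERENCE[start + 1:]:
            if candidate in WIDTH_MODELS and not has_width:
                continue
            t = taxon if candidate in TAXON_MODELS else None
            r = region if candidate in REGION_MODELS else None
            if candidate in TAXON_MODELS and taxon is None:
                continue
            if candidate in REGION_MODELS and region is None:
                continue
            if self.has_entry(candidate, t, r):
                return candidate
        return None

    def validity_range(self, taxon: str, region: str) -> TaxonRegionMetadata:
        """Sampling metadata (n, families, length/mass ranges) for a combination."""
        key = (normalize_name(taxon), normalize_name(region))
        try:
            return self._meta[key]
        except KeyError:
            raise ParameterLookupError(
                f"no sampling metadata for taxon={taxon!r}, region={region!r}"
            ) from None

    def n_individuals(self, region: str | None = None) -> int:
        """Total sampled individuals, optionally restricted to one region."""
        region = normalize_name(region)
        return sum(
            m.n_individuals
            for m in self._meta.values()
            if region is None or normalize_name(m.region) == region
        )

    # -- serialization -----------------------------------------------------

    def parameters_to_csv(self, path_or_buf) -> None:
        """Write the parameter table in the package CSV dialect (3 d.p.)."""
        rows = [
            {
                "model_id": p.model_id,
                "taxon": p.taxon or "",
                "region": p.region or "",
                "intercept": _fmt(p.intercept, 3),
                "slope_length": _fmt(p.slope_length, 3),
                "slope_width": _fmt(p.slope_width, 3),
                "sig_intercept": p.sig_intercept,
                "sig_length": p.sig_length,
                "sig_width": p.sig_width,
            }
            for p in self._params.values()
        ]
        _write_csv(path_or_buf, _PARAMS_HEADER, rows)

    def metadata_to_csv(self, path_or_buf) -> None:
        rows = [
            {
                "taxon": m.taxon,
                "region": m.region,
                "n_individuals": m.n_individuals,
                "n_families": m.n_families,
                "length_min": _fmt(m.length_range[0], 2),
                "length_max": _fmt(m.length_range[1], 2),
                "mass_min": _fmt(m.mass_range[0], 2),
                "mass_max": _fmt(m.mass_range[1], 2),
            }
            for m in self._meta.values()
        ]
        _write_csv(path_or_buf, _META_HEADER, rows)


def _write_csv(path_or_buf, header, rows) -> None:
    def dump(fh):
        writer = csv.DictWriter(fh, fieldnames=header, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)

    if hasattr(path_or_buf, "write"):
        dump(path_or_buf)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="") as fh:
            dump(fh)


def _read_parameter_csv(source) -> list[ParameterSet]:
    if isinstance(source, Path):
        fh = open(source, encoding="utf-8", newline="")
    else:  # str content
        fh = io.StringIO(source)
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _PARAMS_HEADER:
            raise IntegrityError(
                f"parameter CSV header {reader.fieldnames} != expected {_PARAMS_HEADER}"
            )
        out = []
        for row in reader:
            try:
                out.append(
                    ParameterSet(
                        model_id=row["model_id"].strip(),
                        taxon=row["taxon"].strip() or None,
                        region=row["region"].strip() or None,
                        intercept=float(row["intercept"]),
                        slope_length=float(row["slope_length"]),
                        slope_width=float(row["slope_width"]) if row["slope_width"].strip() else None,
                        sig_intercept=row["sig_intercept"].strip(),
                        sig_length=row["sig_length"].strip(),
                        sig_width=row["sig_width"].strip(),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise IntegrityError(f"bad parameter row {row}: {exc}") from exc
    return out


def _read_metadata_csv(source) -> list[TaxonRegionMetadata]:
    if isinstance(source, Path):
        fh = open(source, encoding="utf-8", newline="")
    else:
        fh = io.StringIO(source)
    with fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _META_HEADER:
            raise IntegrityError(
                f"metadata CSV header {reader.fieldnames} != expected {_META_HEADER}"
            )
        out = []
        for row in reader:
            try:
                out.append(
                    TaxonRegionMetadata(
                        taxon=row["taxon"].strip(),
                        region=row["region"].strip(),
                        n_individuals=int(row["n_individuals"]),
                        n_families=int(row["n_families"]),
                        length_range=(float(row["length_min"]), float(row["length_max"])),
                        mass_range=(float(row["mass_min"]), float(row["mass_max"])),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise IntegrityError(f"bad metadata row {row}: {exc}") from exc
    return out


def _data_text(name: str) -> str:
    return resources.files("allomass.data").joinpath(name).read_text(encoding="utf-8")


def load_default_parameters() -> ParameterDatabase:
    """Load the builtin published parameter database, verifying its integrity."""
    params = _read_parameter_csv(_data_text("regression_parameters.csv"))
    meta = _read_metadata_csv(_data_text("taxon_region_metadata.csv"))
    db = ParameterDatabase(params, meta, version=DATABASE_VERSION)
    counts = db.model_counts()
    if counts != _EXPECTED_COUNTS:
        raise IntegrityError(
            f"builtin parameter counts {counts} != expected {_EXPECTED_COUNTS}"
        )
    # every taxon x region equation must have matching LTR row and metadata
    for p in db:
        if p.model_id == "LWTR":
            if not db.has_entry("LTR", p.taxon, p.region):
                raise IntegrityError(f"LWTR row {p.taxon}/{p.region} lacks an LTR row")
            db.validity_range(p.taxon, p.region)
    return db


def published_model_comparison() -> pd.DataFrame:
    """The published eight-model comparison (BIC, dBIC, weights, R2, LOOCV MSE).

    These summary statistics describe fits to the original 6,212-individual
    dataset; they are reference values, not recomputable from this package.
    """
    df = pd.read_csv(io.StringIO(_data_text("model_comparison.csv")))
    if list(df["model_id"]) != list(MODEL_PREFERENCE):
        raise IntegrityError("model comparison table out of order or incomplete")
    return df
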