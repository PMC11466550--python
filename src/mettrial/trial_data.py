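"""Data model and validated long-format CSV I/O for multi-environment trials.

A trial dataset is a tidy table with one row per harvested plot: the
environment (location) it was grown in, the genotype, the replicate (block
within environment) and one column per measured trait.  Sparsity — a genotype
absent from a location — is represented by absent rows, never by sentinel
values; a trait not measured on a plot is an empty cell (NaN in memory).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ID_COLUMNS = ["environment", "genotype", "replicate"]

#: Canonical trait vocabulary, in canonical column order.
TRAIT_COLUMNS = [
    "stem_diameter_mm",
    "ear_height_m",
    "plant_height_m",
    "rows_per_ear",
    "grains_per_row",
    "grains_per_ear",
    "ear_weight_kg",
    "grain_moisture_pct",
    "grain_yield_t_ha",
]

#: Traits that are counts and therefore must be non-negative.
COUNT_TRAITS = {"rows_per_ear", "grains_per_row", "grains_per_ear"}

MATERIAL_CLASSES = {"single_cross", "double_cross", "national_hybrid", "composite"}


class TrialDataError(ValueError):
    """Base class for trial-data problems."""


class FormatError(TrialDataError):
    """A file does not have the expected layout (missing/unparseable columns)."""


class IntegrityError(TrialDataError):
    """Internal consistency violated (duplicate plots, unresolvable labels)."""


class UnknownLabelError(TrialDataError, KeyError):
    """A requested environment/genotype label does not exist in the dataset."""


class TrialDataWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PlotConfig:
    """Plot-level constants needed to standardize grain yield.

    npa_m2
        Net harvested plot area in m^2.  Must be supplied by the analyst:
        it is a property of the field layout, not of the data file.
    hr_pct
        Standard (commercial) grain moisture the yield is corrected to, %.
    shelling
        Shelling coefficient: fraction of ear weight that is grain.
    """

    npa_m2: float
    hr_pct: float = 15.0
    shelling: float = 0.8

    def __post_init__(self) -> None:
        if not (self.npa_m2 > 0):
            raise TrialDataError(f"net plot area must be positive, got {self.npa_m2}")
        if not (0 <= self.hr_pct < 100):
            raise TrialDataError(f"standard moisture must be in [0, 100), got {self.hr_pct}")
        if not (0 < self.shelling <= 1):
            raise TrialDataError(f"shelling coefficient must be in (0, 1], got {self.shelling}")


@dataclass(frozen=True)
class GenotypeRecord:
    code: str
    designation: str = ""
    material_class: Optional[str] = None
    origin: str = ""

    def __post_init__(self) -> None:
        if self.material_class is not None and self.material_class not in MATERIAL_CLASSES:
            raise TrialDataError(
                f"unknown material class {self.material_class!r} for {self.code}; "
                f"expected one of {sorted(MATERIAL_CLASSES)}"
            )


@dataclass(frozen=True)
class EnvironmentRecord:
    name: str
    temp_c: Optional[float] = None
    rainfall_mm: Optional[float] = None
    rainy_days: Optional[float] = None
    humidity_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for attr in ("rainfall_mm", "rainy_days", "humidity_pct"):
            v = getattr(self, attr)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise TrialDataError(f"{attr}={v} for {self.name} must be finite and >= 0")
        if self.temp_c is not None and not np.isfinite(self.temp_c):
            raise TrialDataError(f"temp_c for {self.name} must be finite")


@dataclass(frozen=True)
class PlotObservation:
    """One plot: one genotype in one replicate of one environment."""

    environment_id: str
    genotype_id: str
    replicate_id: str
    traits: Mapping[str, float]


@dataclass
class RangeViolation:
    environment: str
    genotype: str
    replicate: str
    trait: str
    value: float
    reason: str


@dataclass
class EnvironmentBalance:
    environment: str
    genotypes: list[str]
    replicates_per_genotype: dict[str, int]
    absent_genotypes: list[str]
    balanced: bool
    unbalanced_pairs: list[tuple[str, str]]


@dataclass
class ValidationReport:
    per_environment: dict[str, EnvironmentBalance]
    range_violations: list[RangeViolation]
    warnings: list[str]

    @property
    def all_balanced(self) -> bool:
        return all(b.balanced for b in self.per_environment.values())


class TrialDataset:
    """A validated multi-environment trial.

    Parameters
    ----------
    observations
        Tidy DataFrame with columns ``environment, genotype, replicate`` plus
        numeric trait columns.  Missing trait values are NaN.
    genotypes, environments
        Optional registries; auto-built from the distinct labels when omitted.
    plot_config
        Constants for yield standardization (may be None for datasets that
        never touch ear weight).
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        genotypes: Optional[Sequence[GenotypeRecord]] = None,
        environments: Optional[Sequence[EnvironmentRecord]] = None,
        plot_config: Optional[PlotConfig] = None,
    ) -> None:
        df = observations.copy()
        missing = [c for c in ID_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        for c in ID_COLUMNS:
            df[c] = df[c].astype(str)
        trait_cols = [c for c in df.columns if c not in ID_COLUMNS]
        for c in trait_cols:
            df[c] = pd.to_numeric(df[c], errors="raise")
            bad = np.isinf(df[c].to_numpy(dtype=float, na_value=np.nan))
            if bad.any():
                raise IntegrityError(f"non-finite value in trait column {c!r}")
        dup = df.duplicated(subset=ID_COLUMNS, keep=False)
        if dup.any():
            triples = (
                df.loc[dup, ID_COLUMNS].drop_duplicates().itertuples(index=False, name=None)
            )
            listing = ", ".join(f"({e}, {g}, {r})" for e, g, r in triples)
            raise IntegrityError(f"duplicate (environment, genotype, replicate): {listing}")
        df = df.reset_index(drop=True)

        if genotypes is None:
            genotypes = [GenotypeRecord(code=g) for g in sorted(df["genotype"].unique())]
        if environments is None:
            environments = [EnvironmentRecord(name=e) for e in sorted(df["environment"].unique())]
        geno_codes = [g.code for g in genotypes]
        env_names = [e.name for e in environments]
        if len(set(geno_codes)) != len(geno_codes):
            raise IntegrityError("duplicate genotype codes in registry")
        if len(set(env_names)) != len(env_names):
            raise IntegrityError("duplicate environment names in registry")
        unresolved_g = set(df["genotype"]) - set(geno_codes)
        if unresolved_g:
            raise IntegrityError(f"observations reference unknown genotypes: {sorted(unresolved_g)}")
        unresolved_e = set(df["environment"]) - set(env_names)
        if unresolved_e:
            raise IntegrityError(
                f"observations reference unknown environments: {sorted(unresolved_e)}"
            )

        self.observations = df
        self.genotypes = list(genotypes)
        self.environments = list(environments)
        self.plot_config = plot_config

    # -- conveniences -----------------------------------------------------

    @property
    def genotype_codes(self) -> list[str]:
        return [g.code for g in self.genotypes]

    @property
    def environment_names(self) -> list[str]:
        return [e.name for e in self.environments]

    @property
    def trait_names(self) -> list[str]:
        return [c for c in self.observations.columns if c not in ID_COLUMNS]

    def __len__(self) -> int:
        return len(self.observations)

    def iter_observations(self) -> Iterator[PlotObservation]:
        trait_cols = self.trait_names
        for row in self.observations.itertuples(index=False):
            d = row._asdict()
            traits = {t: d[t] for t in trait_cols if pd.notna(d[t])}
            yield PlotObservation(d["environment"], d["genotype"], d["replicate"], traits)

    def with_observations(self, df: pd.DataFrame) -> "TrialDataset":
        """New dataset sharing registries/config but holding ``df``."""
        present_g = set(df["genotype"])
        present_e = set(df["environment"])
        return TrialDataset(
            df,
            genotypes=[g for g in self.genotypes if g.code in present_g],
            environments=[e for e in self.environments if e.name in present_e],
            plot_config=self.plot_config,
        )


# ---------------------------------------------------------------------------
# CSV I/O


def _coerce_decimal(series: pd.Series, column: str) -> pd.Series:
    """Parse a trait column accepting both '.' and ',' decimal separators."""
    raw = series.astype("string").str.strip().str.replace(",", ".", regex=False)
    raw = raw.replace({"": pd.NA, "-": pd.NA, "–": pd.NA})
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"non-numeric value {series.iloc[i]!r} in column {column!r}, data row {i + 1}"
        )
    return out.astype(float)


def read_trial_csv(
    path,
    plot_config: Optional[PlotConfig] = None,
    genotypes: Optional[Sequence[GenotypeRecord]] = None,
    environments: Optional[Sequence[EnvironmentRecord]] = None,
) -> TrialDataset:
    """Read a long-format trial CSV into a validated :class:`TrialDataset`.

    The header must contain ``environment, genotype, replicate``; every other
    column is treated as a trait.  Columns outside the canonical vocabulary
    are preserved with a warning.  Decimal commas are accepted on input.
    """
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    trait_cols = [c for c in df.columns if c not in ID_COLUMNS]
    unknown = [c for c in trait_cols if c not in TRAIT_COLUMNS]
    if unknown:
        warnings.warn(
            f"unknown trait column(s) preserved as-is: {', '.join(unknown)}", TrialDataWarning
        )
    for c in trait_cols:
        df[c] = _coerce_decimal(df[c], c)
    if df.empty:
        warnings.warn("file contains a header but no observations", TrialDataWarning)
    return TrialDataset(df, genotypes=genotypes, environments=environments, plot_config=plot_config)


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write a dataset back to canonical long-format CSV.

    Values are emitted with 6 significant digits and '.' decimals; missing
    traits become empty cells, so read(write(d)) reproduces d.
    """
    cols = ID_COLUMNS + [c for c in TRAIT_COLUMNS if c in dataset.observations.columns]
    cols += [c for c in dataset.observations.columns if c not in cols]
    dataset.observations[cols].to_csv(path, index=False, float_format="%.6g")


def read_genotype_registry(path) -> list[GenotypeRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    if "code" not in df.columns:
        raise FormatError("genotype registry needs a 'code' column")
    return [
        GenotypeRecord(
            code=r.get("code", ""),
            designation=r.get("designation", ""),
            material_class=r.get("material_class") or None,
            origin=r.get("origin", ""),
        )
        for r in df.to_dict("records")
    ]


def read_environment_registry(path) -> list[EnvironmentRecord]:
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise FormatError("environment registry needs a 'name' column")

    def _f(v):
        return None if pd.isna(v) else float(v)

    return [
        EnvironmentRecord(
            name=str(r["name"]),
            temp_c=_f(r.get("temp_c")),
            rainfall_mm=_f(r.get("rainfall_mm")),
            rainy_days=_f(r.get("rainy_days")),
            humidity_pct=_f(r.get("humidity_pct")),
        )
        for r in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# Validation and subsetting


def _check_range(trait: str, value: float) -> Optional[str]:
    if pd.isna(value):
        return None
    if not np.isfinite(value):
        return "non-finite"
    if trait in COUNT_TRAITS and value < 0:
        return "negative count"
    if trait == "grain_moisture_pct" and not (0 <= value < 100):
        return "moisture outside [0, 100)"
    if trait in ("ear_weight_kg", "grain_yield_t_ha") and value < 0:
        return "negative weight/yield"
    return None


def validate_dataset(dataset: TrialDataset) -> ValidationReport:
    """Report per-environment balance and trait-range problems.

    Pure: never mutates the dataset.  An environment is *balanced* when every
    genotype present in it appears in all of that environment's replicates;
    genotypes entirely absent from an environment are listed separately and do
    not break balance (a sparse design is still a valid RCBD per location).
    """
    df = dataset.observations
    per_env: dict[str, EnvironmentBalance] = {}
    notes: list[str] = []
    for env in dataset.environment_names:
        sub = df[df["environment"] == env]
        reps = sorted(sub["replicate"].unique())
        counts = sub.groupby("genotype")["replicate"].nunique().to_dict()
        present = sorted(counts)
        absent = [g for g in dataset.genotype_codes if g not in counts]
        bad = [(env, g) for g, n in counts.items() if n != len(reps)]
        per_env[env] = EnvironmentBalance(
            environment=env,
            genotypes=present,
            replicates_per_genotype=counts,
            absent_genotypes=absent,
            balanced=not bad and bool(present),
            unbalanced_pairs=bad,
        )
        if absent:
            notes.append(f"{env}: genotype(s) absent: {', '.join(absent)}")
        if bad:
            notes.append(
                f"{env}: incomplete replication for " + ", ".join(g for _, g in bad)
            )
    if df.empty:
        notes.append("dataset has zero observations")

    violations: list[RangeViolation] = []
    for trait in dataset.trait_names:
        vals = df[trait]
        for i in vals.index[vals.notna()]:
            reason = _check_range(trait, float(vals.at[i]))
            if reason:
                violations.append(
                    RangeViolation(
                        environment=df.at[i, "environment"],
                        genotype=df.at[i, "genotype"],
                        replicate=df.at[i, "replicate"],
                        trait=trait,
                        value=float(vals.at[i]),
                        reason=reason,
                    )
                )
    return ValidationReport(per_environment=per_env, range_violations=violations, warnings=notes)


def subset_by_environment(dataset: TrialDataset, environment_id: str) -> TrialDataset:
    """Restrict a dataset to a single environment (registries filtered too)."""
    if environment_id not in dataset.environment_names:
        raise UnknownLabelError(environment_id)
    sub = dataset.observations[dataset.observations["environment"] == environment_id]
    return TrialDataset(
        sub.reset_index(drop=True),
        genotypes=[g for g in dataset.genotypes if g.code in set(sub["genotype"])],
        environments=[e for e in dataset.environments if e.name == environment_id],
        plot_config=dataset.plot_config,
    )
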