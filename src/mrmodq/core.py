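"""Summary-data containers, I/O, ratio estimates and instrument-strength summaries.

Two-sample summary-data Mendelian randomization operates on a harmonized
per-SNP table: for each of L uncorrelated variants, an estimated SNP-exposure
association (beta_exposure, with standard error se_exposure) from one sample
and an estimated SNP-outcome association (beta_outcome, se_outcome) from an
independent, non-overlapping sample of the same source population. Binary
outcomes are modelled on the log-odds scale with a normal approximation.

Harmonization itself (effect-allele alignment, palindromic SNPs, LD clumping)
is assumed done upstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryData",
    "SchemaError",
    "DataValidationError",
    "load_summary_data",
    "write_summary_data",
    "ratio_estimates",
    "mean_f_statistic",
]

#: canonical column names of the native TSV schema
NATIVE_COLUMNS = ("snp", "beta_exposure", "se_exposure", "beta_outcome", "se_outcome")

#: accepted aliases per canonical column (TwoSampleMR-style harmonized names included)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "snp": ("snp", "SNP", "snp_id", "rsid"),
    "beta_exposure": ("beta_exposure", "beta.exposure", "gamma_hat", "bx"),
    "se_exposure": ("se_exposure", "se.exposure", "se_x", "bxse"),
    "beta_outcome": ("beta_outcome", "beta.outcome", "big_gamma_hat", "by"),
    "se_outcome": ("se_outcome", "se.outcome", "se_y", "byse"),
}


class SchemaError(ValueError):
    """Input table does not expose the required columns."""


class DataValidationError(ValueError):
    """Input values violate a per-SNP invariant (named SNP in the message)."""


@dataclass(frozen=True)
class SummaryData:
    """Harmonized two-sample MR summary statistics for L uncorrelated SNPs.

    Parameters
    ----------
    snp_id
        Unique variant identifiers, order preserved from input.
    beta_exposure, se_exposure
        SNP-exposure association estimates and standard errors. ``se_exposure``
        may be 0 (the no-measurement-error, NOME, limit); ``se_outcome`` must
        be strictly positive.
    beta_outcome, se_outcome
        SNP-outcome association estimates (log-odds for binary outcomes) and
        standard errors.
    require_unique_ids
        Internal escape hatch for bootstrap resamples, which legitimately
        repeat SNPs.
    """

    snp_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    require_unique_ids: dataclasses.InitVar[bool] = True

    def __post_init__(self, require_unique_ids: bool) -> None:
        arrays = {
            name: np.asarray(getattr(self, name), dtype=float)
            for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")
        }
        ids = np.asarray(self.snp_id, dtype=object)
        object.__setattr__(self, "snp_id", ids)
        for name, arr in arrays.items():
            if arr.ndim != 1 or arr.shape[0] != ids.shape[0]:
                raise DataValidationError(f"column '{name}' is not aligned with snp ids")
            object.__setattr__(self, name, arr)
        if ids.shape[0] < 1:
            raise DataValidationError("at least one SNP is required")
        if require_unique_ids and len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if list(ids).count(s) > 1})
            raise DataValidationError(f"duplicate snp ids: {dupes}")
        for name in ("beta_exposure", "beta_outcome"):
            bad = ~np.isfinite(arrays[name])
            if bad.any():
                raise DataValidationError(
                    f"non-finite {name} for SNP {ids[bad][0]!r}"
                )
        bad = ~(arrays["se_exposure"] >= 0) | ~np.isfinite(arrays["se_exposure"])
        if bad.any():
            raise DataValidationError(f"negative or non-finite se_exposure for SNP {ids[bad][0]!r}")
        bad = ~(arrays["se_outcome"] > 0) | ~np.isfinite(arrays["se_outcome"])
        if bad.any():
            raise DataValidationError(f"non-positive se_outcome for SNP {ids[bad][0]!r}")

    @property
    def L(self) -> int:
        """Number of instruments."""
        return int(self.snp_id.shape[0])

    def __len__(self) -> int:
        return self.L

    def take(self, index) -> "SummaryData":
        """Subset/resample by positional index (bootstrap resamples may repeat)."""
        idx = np.asarray(index)
        repeated = len(set(self.snp_id[idx])) != len(idx)
        return SummaryData(
            self.snp_id[idx],
            self.beta_exposure[idx],
            self.se_exposure[idx],
            self.beta_outcome[idx],
            self.se_outcome[idx],
            require_unique_ids=not repeated,
        )

    def drop(self, snp: str) -> "SummaryData":
        """Return the dataset with one named SNP removed."""
        keep = self.snp_id != snp
        if keep.all():
            raise KeyError(snp)
        return self.take(np.nonzero(keep)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_id,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
            }
        )

    def to_json(self) -> str:
        payload = {k: list(v) if k == "snp" else [float(x) for x in v]
                   for k, v in self.to_frame().items()}
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SummaryData":
        payload = json.loads(text)
        return cls(
            np.asarray(payload["snp"], dtype=object),
            np.asarray(payload["beta_exposure"], float),
            np.asarray(payload["se_exposure"], float),
            np.asarray(payload["beta_outcome"], float),
            np.asarray(payload["se_outcome"], float),
        )


def _resolve_columns(columns, column_map: dict[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual file columns; raise SchemaError naming misses."""
    resolved: dict[str, str] = {}
    column_map = column_map or {}
    for canonical in NATIVE_COLUMNS:
        if canonical in column_map:
            candidate = column_map[canonical]
            if candidate not in columns:
                raise SchemaError(
                    f"mapped column '{candidate}' (for '{canonical}') not found in input"
                )
            resolved[canonical] = candidate
            continue
        for alias in COLUMN_ALIASES[canonical]:
            if alias in columns:
                resolved[canonical] = alias
                break
        else:
            raise SchemaError(f"required column '{canonical}' missing from input")
    return resolved


def load_summary_data(source, column_map: dict[str, str] | None = None) -> SummaryData:
    """Read a harmonized summary-statistics table into a :class:`SummaryData`.

    ``source`` may be a path to a TSV file (header row, '.' decimal, UTF-8) or
    a :class:`pandas.DataFrame`. Column names may follow the native schema
    (``snp, beta_exposure, se_exposure, beta_outcome, se_outcome``), the
    TwoSampleMR-style dotted names, or be supplied via ``column_map``
    (canonical name -> file column).
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(Path(source), sep="\t", float_precision="round_trip")
    resolved = _resolve_columns(list(frame.columns), column_map)
    ds = SummaryData(
        frame[resolved["snp"]].to_numpy(dtype=object),
        frame[resolved["beta_exposure"]].to_numpy(dtype=float),
        frame[resolved["se_exposure"]].to_numpy(dtype=float),
        frame[resolved["beta_outcome"]].to_numpy(dtype=float),
        frame[resolved["se_outcome"]].to_numpy(dtype=float),
    )
    logger.info("loaded %d SNPs (columns: %s)", ds.L, resolved)
    return ds


def write_summary_data(ds: SummaryData, path) -> None:
    """Write the native TSV schema; floats use shortest round-trip repr."""
    frame = ds.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(NATIVE_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join([str(row.snp)] + [repr(float(v)) for v in row[1:]]) + "\n")


def ratio_estimates(ds: SummaryData) -> np.ndarray:
    """Per-SNP Wald ratio estimates beta_j = beta_outcome / beta_exposure.

    Each ratio is the causal effect implied by a single valid instrument.
    SNPs with a zero exposure association have an undefined ratio and are
    rejected (filter upstream; silent dropping would change L and the Q
    degrees of freedom).
    """
    zero = ds.beta_exposure == 0
    if zero.any():
        raise ZeroDivisionError(
            f"zero beta_exposure for SNP {ds.snp_id[zero][0]!r}: ratio undefined"
        )
    return ds.beta_outcome / ds.beta_exposure


def mean_f_statistic(ds: SummaryData) -> float:
    """Mean single-instrument F statistic, (1/L) sum_j beta_exposure_j^2 / se_exposure_j^2.

    The conventional summary of instrument strength: values near 10 signal a
    weak-instrument regime in which the no-measurement-error assumption is
    badly violated.
    """
    if (ds.se_exposure == 0).any():
        return float(np.inf) if (ds.beta_exposure[ds.se_exposure == 0] != 0).any() else 0.0
    return float(np.mean(ds.beta_exposure**2 / ds.se_exposure**2))
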