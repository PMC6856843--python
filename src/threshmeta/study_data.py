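"""Data model, long-format CSV I/O and validation for multi-threshold
diagnostic test accuracy count data.

A study reports, for each of its two patient populations (disease-free and
diseased), the group size ``N`` and the number of patients whose continuous
test result exceeds each of a set of thresholds.  Higher results are taken
to indicate disease, so both the false positive count (disease-free group)
and the true positive count (diseased group) must be non-increasing as the
threshold rises.  Counts are of results *strictly greater than* the
threshold; the >/>= distinction is fixed, not configurable.

The canonical on-disk format is a long CSV with one row per
study x group x threshold and columns ``study_id, group, N, threshold,
count_above``.  Group labels ``0``/``disease_free``/``control`` and
``1``/``diseased``/``case`` are normalised internally to j=1 (disease-free)
and j=2 (diseased).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DISEASE_FREE = 1
DISEASED = 2

#: accepted spellings of the two groups in input files
_GROUP_ALIASES = {
    "0": DISEASE_FREE,
    "1": DISEASED,
    "disease_free": DISEASE_FREE,
    "disease-free": DISEASE_FREE,
    "diseased": DISEASED,
    "control": DISEASE_FREE,
    "case": DISEASED,
}
_GROUP_NAMES = {DISEASE_FREE: "disease_free", DISEASED: "diseased"}

_REQUIRED_COLUMNS = ["study_id", "group", "N", "threshold", "count_above"]


class DataFormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class DataValidationError(ValueError):
    """Raised when counts violate the structural constraints of the data."""


def _normalise_group(value) -> int:
    key = str(value).strip().lower()
    try:
        return _GROUP_ALIASES[key]
    except KeyError:
        raise DataFormatError(
            f"unrecognised group label {value!r}; expected one of "
            f"{sorted(set(_GROUP_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class ThresholdCounts:
    """Counts above each reported threshold for one study-group.

    Parameters
    ----------
    study_id : str
        Opaque study label.
    group : int
        1 for the disease-free population, 2 for the diseased population.
    n : int
        Total number of patients in the group.
    thresholds : ndarray of float
        Strictly increasing threshold values, in the units of the test.
    counts_above : ndarray of int
        Number of patients with test result above each threshold;
        non-increasing along the threshold sequence.
    """

    study_id: str
    group: int
    n: int
    thresholds: np.ndarray
    counts_above: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "thresholds", np.asarray(self.thresholds, dtype=float))
        object.__setattr__(self, "counts_above", np.asarray(self.counts_above, dtype=int))
        if self.group not in (DISEASE_FREE, DISEASED):
            raise DataValidationError(
                f"study {self.study_id!r}: group must be 1 or 2, got {self.group}"
            )
        if self.n <= 0:
            raise DataValidationError(f"study {self.study_id!r}: N must be positive")
        if self.thresholds.ndim != 1 or self.thresholds.size == 0:
            raise DataValidationError(
                f"study {self.study_id!r}: at least one threshold is required"
            )
        if self.counts_above.shape != self.thresholds.shape:
            raise DataValidationError(
                f"study {self.study_id!r}: thresholds and counts differ in length"
            )
        d = np.diff(self.thresholds)
        if np.any(d <= 0):
            which = "duplicated" if np.any(d == 0) else "non-increasing"
            raise DataValidationError(
                f"study {self.study_id!r} group {_GROUP_NAMES[self.group]}: "
                f"{which} thresholds"
            )
        x = self.counts_above
        if np.any(x < 0) or np.any(x > self.n):
            raise DataValidationError(
                f"study {self.study_id!r} group {_GROUP_NAMES[self.group]}: "
                f"counts must lie in [0, N]"
            )
        if np.any(np.diff(x) > 0):
            raise DataValidationError(
                f"study {self.study_id!r} group {_GROUP_NAMES[self.group]}: "
                f"counts above threshold must be non-increasing in threshold"
            )

    @property
    def n_thresholds(self) -> int:
        return self.thresholds.size


@dataclass(frozen=True)
class CovariateRecord:
    """Study-level covariate values (e.g. average patient age in years)."""

    study_id: str
    values: dict

    def __post_init__(self):
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise DataValidationError(
                    f"study {self.study_id!r}: covariate {name!r} is not finite"
                )


@dataclass
class MetaDataset:
    """A collection of studies, each contributing both populations.

    The two groups of a study may report different threshold sets; the
    binomial factorisation of the likelihood works per group, so partially
    reported cells are handled naturally.
    """

    records: list[ThresholdCounts]
    covariates: list[CovariateRecord] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, set[int]] = {}
        for rec in self.records:
            groups = seen.setdefault(rec.study_id, set())
            if rec.group in groups:
                raise DataValidationError(
                    f"study {rec.study_id!r}: duplicated group "
                    f"{_GROUP_NAMES[rec.group]}"
                )
            groups.add(rec.group)
        for sid, groups in seen.items():
            if groups != {DISEASE_FREE, DISEASED}:
                raise DataValidationError(
                    f"study {sid!r}: both disease-free and diseased groups "
                    f"are required"
                )
        cov_ids = {c.study_id for c in self.covariates}
        extra = cov_ids - set(seen)
        if extra:
            raise DataValidationError(
                f"covariates reference unknown studies: {sorted(extra)}"
            )

    @property
    def study_ids(self) -> list[str]:
        out, seen = [], set()
        for rec in self.records:
            if rec.study_id not in seen:
                seen.add(rec.study_id)
                out.append(rec.study_id)
        return out

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def record(self, study_id: str, group: int) -> ThresholdCounts:
        for rec in self.records:
            if rec.study_id == study_id and rec.group == group:
                return rec
        raise KeyError((study_id, group))

    def covariate_frame(self) -> pd.DataFrame | None:
        """Covariates as a DataFrame indexed by study_id, or None."""
        if not self.covariates:
            return None
        rows = {c.study_id: c.values for c in self.covariates}
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("study_id")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view, canonically sorted."""
        rows = []
        for sid in self.study_ids:
            for group in (DISEASE_FREE, DISEASED):
                rec = self.record(sid, group)
                for c, x in zip(rec.thresholds, rec.counts_above):
                    rows.append(
                        dict(
                            study_id=sid,
                            group=_GROUP_NAMES[group],
                            N=rec.n,
                            threshold=c,
                            count_above=int(x),
                        )
                    )
        return pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)


def read_dataset(path, covariate_path=None) -> MetaDataset:
    """Read a long-format count CSV (and optional covariate CSV).

    Rows are grouped by (study, group) and sorted by threshold before
    validation, so the input row order does not matter.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required columns {missing}")
    records = []
    df = df.assign(_group=[_normalise_group(g) for g in df["group"]])
    for (sid, group), sub in df.groupby(["study_id", "_group"], sort=False):
        sub = sub.sort_values("threshold")
        n_vals = sub["N"].unique()
        if len(n_vals) != 1:
            raise DataValidationError(
                f"study {sid!r} group {_GROUP_NAMES[group]}: N differs across rows"
            )
        records.append(
            ThresholdCounts(
                study_id=str(sid),
                group=int(group),
                n=int(n_vals[0]),
                thresholds=sub["threshold"].to_numpy(),
                counts_above=sub["count_above"].to_numpy(),
            )
        )
    covariates = []
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path)
        if "study_id" not in cov.columns:
            raise DataFormatError(f"{covariate_path}: missing study_id column")
        value_cols = [c for c in cov.columns if c != "study_id"]
        for _, row in cov.iterrows():
            covariates.append(
                CovariateRecord(
                    study_id=str(row["study_id"]),
                    values={c: float(row[c]) for c in value_cols},
                )
            )
    return MetaDataset(records=records, covariates=covariates)


def write_dataset(dataset: MetaDataset, path, covariate_path=None) -> None:
    """Write the canonical long CSV (and optionally the covariate CSV)."""
    dataset.to_frame().to_csv(path, index=False)
    if covariate_path is not None and dataset.covariates:
        frame = dataset.covariate_frame().reset_index()
        frame.to_csv(covariate_path, index=False)


def from_accuracy(
    n_disease_free: int,
    n_diseased: int,
    thresholds,
    sens,
    spec,
    study_id: str = "study_1",
) -> MetaDataset:
    """Build a single-study dataset from sensitivity/specificity fractions.

    Counts are recovered by rounding ``sens * N_diseased`` and
    ``(1 - spec) * N_disease_free``; if rounding breaks the required
    monotonicity of counts the caller must resolve the conflict, and a
    validation error is raised rather than guessing.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    sens = np.asarray(sens, dtype=float)
    spec = np.asarray(spec, dtype=float)
    if not (thresholds.shape == sens.shape == spec.shape):
        raise DataValidationError("thresholds, sens and spec must share a length")
    if np.any((sens < 0) | (sens > 1)) or np.any((spec < 0) | (spec > 1)):
        raise DataValidationError("sensitivities and specificities must lie in [0,1]")
    x_diseased = np.rint(sens * n_diseased).astype(int)
    x_free = np.rint((1.0 - spec) * n_disease_free).astype(int)
    records = [
        ThresholdCounts(study_id, DISEASE_FREE, n_disease_free, thresholds, x_free),
        ThresholdCounts(study_id, DISEASED, n_diseased, thresholds, x_diseased),
    ]
    return MetaDataset(records=records)


def conditional_counts(tc: ThresholdCounts) -> list[tuple[int, int]]:
    """(trials, successes) pairs of the binomial factorisation.

    The multinomial spread of one group's results across the T+1 intervals
    cut by its thresholds factorises into a chain of conditional binomials:
    the count above the first threshold out of N, then each subsequent
    count out of the previous one.
    """
    x = tc.counts_above
    trials = np.concatenate(([tc.n], x[:-1]))
    return list(zip(trials.tolist(), x.tolist()))
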