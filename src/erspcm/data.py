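"""Response-data container, long-format CSV readers and validation.

The canonical on-disk layout is long format: one row per observed
(person, item) cell with columns ``person_id, country_id, item_id, response``
plus a separate covariate table ``country_id, x`` (e.g. HDI). The raw
covariate is standardized once at read time (mean 0, SD 1 with denominator
G-1) and the transform recorded so raw-scale values can be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseDataset",
    "read_and_validate",
    "wide_to_long",
    "standardize_covariate",
    "ValidationError",
    "OutOfRangeResponseError",
    "DuplicateCellError",
    "AmbiguousCountryError",
    "MissingCovariateError",
]

MISSING = 0  # internal code for a missing cell (responses are 1..K)


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class OutOfRangeResponseError(ValidationError):
    """A response falls outside 1..K."""


class DuplicateCellError(ValidationError):
    """A (person, item) pair occurs more than once."""


class AmbiguousCountryError(ValidationError):
    """A person is listed under more than one country."""


class MissingCovariateError(ValidationError):
    """A country in the response file has no covariate row."""


def standardize_covariate(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize to sample mean 0 and sample SD 1 (denominator G-1).

    Returns (standardized values, mean, sd).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("covariate standardization needs at least 2 countries")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValidationError("covariate has zero variance; cannot standardize")
    return (values - mean) / sd, mean, sd


@dataclass
class ResponseDataset:
    """Ordinal responses of persons nested in countries.

    Attributes
    ----------
    responses : int array (n_persons, n_items)
        Categories 1..K; 0 marks a missing cell.
    country : int array (n_persons,)
        Country index of each person, 0..G-1.
    K : int
        Number of response categories.
    x : array (G,) or None
        Standardized country covariate (mean 0, SD 1).
    """

    responses: np.ndarray
    country: np.ndarray
    K: int
    x: Optional[np.ndarray] = None
    person_ids: Optional[Sequence] = None
    country_ids: Optional[Sequence] = None
    item_ids: Optional[Sequence] = None
    covariate_mean: Optional[float] = None
    covariate_sd: Optional[float] = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        self.country = np.asarray(self.country, dtype=np.int64)
        self.K = int(self.K)
        if self.responses.ndim != 2:
            raise ValidationError("responses must be a (n_persons, n_items) matrix")
        n = self.responses.shape[0]
        if self.country.shape != (n,):
            raise ValidationError("country must have one entry per person")
        if self.responses.min(initial=0) < 0 or self.responses.max(initial=0) > self.K:
            bad = np.argwhere((self.responses < 0) | (self.responses > self.K))[0]
            raise OutOfRangeResponseError(
                f"response {self.responses[tuple(bad)]} outside 1..{self.K} at "
                f"person index {bad[0]}, item index {bad[1]}"
            )
        if self.person_ids is None:
            self.person_ids = list(range(n))
        if self.country_ids is None:
            self.country_ids = list(range(self.n_countries))
        if self.item_ids is None:
            self.item_ids = list(range(self.n_items))
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != (self.n_countries,):
                raise ValidationError(
                    f"covariate has {self.x.shape} entries for "
                    f"{self.n_countries} countries"
                )

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_countries(self) -> int:
        return int(self.country.max()) + 1 if self.country.size else 0

    @property
    def observed_mask(self) -> np.ndarray:
        return self.responses >= 1

    def persons_per_country(self) -> np.ndarray:
        return np.bincount(self.country, minlength=self.n_countries)

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame of observed cells only."""
        p, i = np.nonzero(self.observed_mask)
        return pd.DataFrame(
            {
                "person_id": np.asarray(self.person_ids, dtype=object)[p],
                "country_id": np.asarray(self.country_ids, dtype=object)[
                    self.country[p]
                ],
                "item_id": np.asarray(self.item_ids, dtype=object)[i],
                "response": self.responses[p, i],
            }
        )

    def covariate_frame(self) -> pd.DataFrame:
        if self.x is None:
            raise ValidationError("dataset has no covariate")
        return pd.DataFrame({"country_id": list(self.country_ids), "x": self.x})

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        K: int,
        covariates: Optional[pd.DataFrame] = None,
        standardize: bool = True,
    ) -> "ResponseDataset":
        """Build a dataset from a long-format frame, validating as it goes."""
        required = {"person_id", "country_id", "item_id", "response"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise ValidationError(f"long format is missing columns {sorted(missing_cols)}")
        df = df.copy()
        df["response"] = pd.to_numeric(df["response"])

        out_of_range = (df["response"] < 1) | (df["response"] > K)
        if out_of_range.any():
            row = int(np.argmax(out_of_range.to_numpy()))
            raise OutOfRangeResponseError(
                f"response {df['response'].iloc[row]} outside 1..{K} at data "
                f"row {row} (person_id={df['person_id'].iloc[row]!r}, "
                f"item_id={df['item_id'].iloc[row]!r})"
            )

        dup = df.duplicated(subset=["person_id", "item_id"])
        if dup.any():
            row = int(np.argmax(dup.to_numpy()))
            raise DuplicateCellError(
                f"duplicate (person, item) cell at data row {row}: "
                f"person_id={df['person_id'].iloc[row]!r}, "
                f"item_id={df['item_id'].iloc[row]!r}"
            )

        pc = df[["person_id", "country_id"]].drop_duplicates()
        counts = pc.groupby("person_id", sort=False)["country_id"].nunique()
        if (counts > 1).any():
            offender = counts[counts > 1].index[0]
            raise AmbiguousCountryError(
                f"person_id={offender!r} is listed under more than one country"
            )

        person_ids = list(pd.unique(df["person_id"]))
        country_ids = list(pd.unique(df["country_id"]))
        item_ids = list(pd.unique(df["item_id"]))
        p_index = {p: i for i, p in enumerate(person_ids)}
        c_index = {c: i for i, c in enumerate(country_ids)}
        i_index = {it: i for i, it in enumerate(item_ids)}

        responses = np.full((len(person_ids), len(item_ids)), MISSING, dtype=np.int64)
        country = np.zeros(len(person_ids), dtype=np.int64)
        for pid, cid in pc.itertuples(index=False):
            country[p_index[pid]] = c_index[cid]
        rows = df["person_id"].map(p_index).to_numpy()
        cols = df["item_id"].map(i_index).to_numpy()
        responses[rows, cols] = df["response"].to_numpy()

        x = cov_mean = cov_sd = None
        if covariates is not None:
            cov_cols = list(covariates.columns)
            if "country_id" not in cov_cols or len(cov_cols) < 2:
                raise ValidationError(
                    "covariate table needs a 'country_id' column and a value column"
                )
            value_col = [c for c in cov_cols if c != "country_id"][0]
            cov_map = dict(
                zip(covariates["country_id"], pd.to_numeric(covariates[value_col]))
            )
            absent = [c for c in country_ids if c not in cov_map]
            if absent:
                raise MissingCovariateError(
                    f"countries without a covariate row: {absent!r}"
                )
            raw = np.array([cov_map[c] for c in country_ids], dtype=float)
            if standardize:
                x, cov_mean, cov_sd = standardize_covariate(raw)
            else:
                x, cov_mean, cov_sd = raw, 0.0, 1.0

        return cls(
            responses=responses,
            country=country,
            K=K,
            x=x,
            person_ids=person_ids,
            country_ids=country_ids,
            item_ids=item_ids,
            covariate_mean=cov_mean,
            covariate_sd=cov_sd,
        )


def wide_to_long(
    wide: pd.DataFrame,
    person_col: str = "person_id",
    country_col: str = "country_id",
    item_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Convert a wide persons x items table to the canonical long format."""
    if item_cols is None:
        item_cols = [c for c in wide.columns if c not in (person_col, country_col)]
    long = wide.melt(
        id_vars=[person_col, country_col],
        value_vars=list(item_cols),
        var_name="item_id",
        value_name="response",
    ).dropna(subset=["response"])
    long = long.rename(columns={person_col: "person_id", country_col: "country_id"})
    return long[["person_id", "country_id", "item_id", "response"]]


def read_and_validate(
    responses_path: str | Path,
    covariates_path: Optional[str | Path],
    K: int,
) -> ResponseDataset:
    """Read long-format response and covariate CSVs into a validated dataset.

    Raises a distinct, named error for each malformation: out-of-range
    response, duplicate (person, item) cell, person in two countries,
    country without a covariate row.
    """
    df = pd.read_csv(responses_path)
    cov = pd.read_csv(covariates_path) if covariates_path is not None else None
    ds = ResponseDataset.from_long(df, K=K, covariates=cov)
    return ds
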