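"""Synthetic study cohorts.

A cohort is a subject table (id, age in years, sex, and implicitly both
hemispheres per subject) emulating a cross-sectional developmental sample:
by default 88 children and adolescents aged 8-19 years with 42 males.

Ages are drawn uniformly over the configured range by default; a
triangular mode skewed towards younger ages is available to mimic cohorts
with denser sampling in late childhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Cohort", "make_cohort"]

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class Cohort:
    """Subject table with one row per subject (both hemispheres implied)."""

    table: pd.DataFrame  # columns: subject_id, age, sex

    def __post_init__(self) -> None:
        required = {"subject_id", "age", "sex"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ages(self) -> np.ndarray:
        return self.table["age"].to_numpy()

    @property
    def sexes(self) -> np.ndarray:
        return self.table["sex"].to_numpy()

    def long_table(self) -> pd.DataFrame:
        """Subject x hemisphere long format (one row per hemisphere)."""
        rows = [self.table.assign(hemisphere=h) for h in HEMISPHERES]
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.long_table().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        long = pd.read_csv(path)
        table = (long.drop(columns=["hemisphere"], errors="ignore")
                 .drop_duplicates("subject_id").reset_index(drop=True))
        return cls(table)


def make_cohort(n: int = 88, age_min: float = 8.0, age_max: float = 19.0,
                male_fraction: float = 42 / 88, seed: int = 0,
                age_distribution: str = "uniform") -> Cohort:
    """Draw a reproducible synthetic cohort.

    Parameters
    ----------
    n : number of subjects (>= 2 so both sexes can be present).
    age_min, age_max : age range in years (inclusive support).
    male_fraction : proportion of males; the male count is round(n * fraction).
    age_distribution : 'uniform' (default) or 'young_skew' (triangular with
        mode at age_min, mimicking denser sampling of late childhood).
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 <= male_fraction <= 1.0):
        raise ValueError("male_fraction must be within [0, 1]")
    if age_max < age_min:
        raise ValueError("age_max must be >= age_min")
    rng = np.random.default_rng(seed)
    if age_distribution == "uniform":
        ages = rng.uniform(age_min, age_max, size=n)
    elif age_distribution == "young_skew":
        ages = rng.triangular(age_min, age_min, age_max, size=n)
    else:
        raise ValueError(f"unknown age_distribution {age_distribution!r}")
    if age_max == age_min:
        ages = np.full(n, float(age_min))
    n_male = int(round(n * male_fraction))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sexes)
    table = pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "age": ages,
        "sex": sexes,
    })
    return Cohort(table)
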