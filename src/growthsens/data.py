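"""Long-format two-wave panel container and person-level views.

The analysis data are student×wave records nested in schools: every student
contributes a wave-0 row (always observed) and a wave-1 row whose outcome may
be missing due to dropout.  ``LongDataset`` wraps the long-format table
together with an optional simulation-truth sidecar (realized random effects
and masked outcomes) that estimators must never touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed-effect terms of the analysis growth model, in parameter order
#: (intercept, time, reasoning, self-concept, time x reasoning, time x sc).
ANALYSIS_TERMS = ("intercept", "time", "reas", "sc", "time:reas", "time:sc")

REQUIRED_COLUMNS = ("school_id", "person_id", "wave", "responded", "outcome")


@dataclass
class LongDataset:
    """Two-wave panel in long format plus an optional truth sidecar.

    Parameters
    ----------
    frame
        One row per person x wave with columns ``school_id``, ``person_id``,
        ``wave`` (0/1), ``responded`` (1 = outcome observed), ``outcome``
        (NaN when masked) and any number of baseline covariate columns
        (constant within person).
    truth
        Person-level table with the realized person effect ``u``, school
        effect ``v`` and the complete wave-1 outcome ``y1_true``.  Purely for
        oracle checks; never written to the analysis-facing CSV.
    meta
        Free-form provenance (generator config, solved dropout intercepts...).
    """

    frame: pd.DataFrame
    truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"long frame is missing required columns: {missing}")
        waves = self.frame.groupby("person_id")["wave"].agg(["size", "sum"])
        if not ((waves["size"] == 2) & (waves["sum"] == 1)).all():
            raise ValueError("every person must have exactly one wave-0 and one wave-1 row")
        w0 = self.frame[self.frame["wave"] == 0]
        if w0["outcome"].notna().any() and w0["outcome"].isna().any():
            raise ValueError("wave-0 outcomes must be all set or all unset")
        if (w0["responded"] != 1).any():
            raise ValueError("wave-0 rows are always observed (responded must be 1)")
        nest = self.frame.groupby("person_id")["school_id"].nunique()
        if (nest > 1).any():
            raise ValueError("person ids must nest uniquely within school ids")

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in REQUIRED_COLUMNS]

    def person_table(self) -> pd.DataFrame:
        """Person-level wide table: covariates + y0, y1, responded."""
        df = self.frame
        w0 = df[df["wave"] == 0].set_index("person_id")
        w1 = df[df["wave"] == 1].set_index("person_id")
        out = w0[["school_id", *self.covariate_columns]].copy()
        out["y0"] = w0["outcome"]
        out["y1"] = w1["outcome"].reindex(out.index)
        out["responded"] = w1["responded"].reindex(out.index).astype(int)
        return out.reset_index()

    def dropout_rate(self) -> float:
        w1 = self.frame[self.frame["wave"] == 1]
        return float(1.0 - w1["responded"].mean())

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path, truth_path: str | Path | None = None) -> None:
        """Write the analysis CSV (missing outcome as empty field) and,
        optionally, the truth sidecar CSV."""
        cols = [*REQUIRED_COLUMNS, *self.covariate_columns]
        self.frame[cols].to_csv(path, index=False, na_rep="")
        if truth_path is not None:
            if self.truth is None:
                raise ValueError("dataset has no truth sidecar to write")
            self.truth.to_csv(truth_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, truth_path: str | Path | None = None) -> "LongDataset":
        frame = pd.read_csv(path)
        truth = pd.read_csv(truth_path) if truth_path is not None else None
        ds = cls(frame=frame, truth=truth)
        ds.validate()
        return ds

    def copy(self) -> "LongDataset":
        return LongDataset(
            frame=self.frame.copy(),
            truth=None if self.truth is None else self.truth.copy(),
            meta=dict(self.meta),
        )


@dataclass
class PersonView:
    """Numeric person-level arrays used by all likelihood code.

    ``y1`` is NaN for dropouts; ``X0``/``X1`` are the wave-0/wave-1 rows of
    the fixed-effect design for each person.
    """

    y0: np.ndarray
    y1: np.ndarray
    resp: np.ndarray
    school: np.ndarray
    X0: np.ndarray
    X1: np.ndarray
    terms: tuple
    person_id: np.ndarray
    school_levels: np.ndarray
    covariates: pd.DataFrame

    @property
    def has_y1(self) -> np.ndarray:
        """Wave-1 outcome present (observed or imputed)."""
        return ~np.isnan(self.y1)

    @property
    def n_persons(self) -> int:
        return self.y0.size

    @property
    def n_schools(self) -> int:
        return self.school_levels.size


def build_design(cov: pd.DataFrame, wave: int, reas_col: str = "reas", sc_col: str = "sc") -> np.ndarray:
    """Design rows of the growth model for one wave (time coded 0/1)."""
    n = len(cov)
    t = float(wave)
    reas = cov[reas_col].to_numpy(float)
    sc = cov[sc_col].to_numpy(float)
    return np.column_stack(
        [np.ones(n), np.full(n, t), reas, sc, t * reas, t * sc]
    )


def person_view(data: LongDataset, reas_col: str = "reas", sc_col: str = "sc") -> PersonView:
    """Collapse a :class:`LongDataset` to person-level arrays.

    Sorting is canonical (school, person), so any row ordering of the input
    produces identical numbers downstream.
    """
    for col in (reas_col, sc_col):
        if col not in data.frame.columns:
            raise ValueError(f"design column '{col}' not present in the data")
    pt = data.person_table().sort_values(["school_id", "person_id"], kind="mergesort")
    school_levels, school = np.unique(pt["school_id"].to_numpy(), return_inverse=True)
    cov = pt.drop(columns=["y0", "y1", "responded"]).reset_index(drop=True)
    X0 = build_design(cov, 0, reas_col, sc_col)
    X1 = build_design(cov, 1, reas_col, sc_col)
    return PersonView(
        y0=pt["y0"].to_numpy(float),
        y1=pt["y1"].to_numpy(float),
        resp=pt["responded"].to_numpy() == 1,
        school=school,
        X0=X0,
        X1=X1,
        terms=ANALYSIS_TERMS,
        person_id=pt["person_id"].to_numpy(),
        school_levels=school_levels,
        covariates=cov,
    )
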