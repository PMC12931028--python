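"""Hierarchical survival data container and delimited-text I/O.

A dataset holds one row per subject with the observed follow-up time, an
event indicator, case-mix covariates, and the surgeon and center the subject
belongs to.  Surgeons are strictly nested within centers: a surgeon label may
appear under exactly one center.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical column roles required in every dataset
ROLES = ("time", "event", "surgeon", "center")


@dataclass(frozen=True)
class SubjectRecord:
    """A single subject's observation: follow-up time, event indicator,
    case-mix covariate vector and cluster membership."""

    time: float
    event: int
    covariates: tuple
    surgeon_id: object
    center_id: object


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class NestingError(ValueError):
    """A surgeon label appears under more than one center."""


@dataclass
class Schema:
    """Maps the canonical column roles onto the columns of a delimited file."""

    time: str = "time"
    event: str = "event"
    surgeon: str = "surgeon"
    center: str = "center"
    covariates: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        cols = cfg.get("columns", cfg)
        return cls(
            time=cols.get("time", "time"),
            event=cols.get("event", "event"),
            surgeon=cols.get("surgeon", "surgeon"),
            center=cols.get("center", "center"),
            covariates=list(cols.get("covariates", [])),
        )


class SurvivalDataset:
    """Three-level hierarchical survival dataset.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per subject with columns ``time``, ``event``, one column per
        covariate, ``surgeon`` and ``center``.
    covariate_names : sequence of str
        Names of the case-mix covariate columns, in model order.

    Attributes
    ----------
    n : int
        Total number of subjects.
    n_centers, n_surgeons : int
        Number of distinct centers / surgeons.
    time, event : ndarray
        Follow-up times and event indicators, length ``n``.
    X : ndarray, shape (n, q)
        Case-mix covariate matrix.
    surgeon_idx, center_idx : ndarray of int
        Per-subject integer codes into ``surgeon_ids`` / ``center_ids``.
    surgeon_center : ndarray of int
        For each surgeon code, the code of its (unique) center.
    """

    def __init__(self, frame: pd.DataFrame, covariate_names):
        self.covariate_names = list(covariate_names)
        frame = frame.reset_index(drop=True)
        self._validate(frame)
        frame = self._drop_zero_time(frame)
        self.frame = frame

        self.time = frame["time"].to_numpy(float)
        self.event = frame["event"].to_numpy(int)
        self.X = (
            frame[self.covariate_names].to_numpy(float)
            if self.covariate_names
            else np.empty((len(frame), 0))
        )

        # surgeon labels are only unique within a center; index them as
        # (center, surgeon) pairs and expose stable integer codes
        center_codes, self.center_ids = pd.factorize(frame["center"], sort=True)
        pair = list(zip(frame["center"], frame["surgeon"]))
        surgeon_codes, pair_ids = pd.factorize(pd.Series(pair), sort=True)
        self.center_idx = center_codes.astype(np.intp)
        self.surgeon_idx = surgeon_codes.astype(np.intp)
        self.surgeon_pairs = list(pair_ids)
        self.surgeon_ids = [s for (_, s) in pair_ids]
        center_of = pd.Series(
            [c for (c, _) in pair_ids]
        ).map({c: i for i, c in enumerate(self.center_ids)})
        self.surgeon_center = center_of.to_numpy(np.intp)

    # -- validation -------------------------------------------------------

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        for col in ("time", "event", "surgeon", "center"):
            if col not in frame.columns:
                raise SchemaError(f"required column {col!r} is missing")
        t = pd.to_numeric(frame["time"], errors="coerce")
        if t.isna().any():
            row = int(t.index[t.isna()][0])
            raise ValueError(f"non-numeric follow-up time at row {row}")
        if (t < 0).any():
            row = int(t.index[t < 0][0])
            raise ValueError(f"negative follow-up time at row {row}")
        ev = pd.to_numeric(frame["event"], errors="coerce")
        bad = ~ev.isin([0, 1])
        if bad.any():
            row = int(ev.index[bad][0])
            raise ValueError(f"event indicator not in {{0, 1}} at row {row}")
        if ((t == 0) & (ev == 1)).any():
            row = int(t.index[(t == 0) & (ev == 1)][0])
            raise ValueError(
                f"event at time 0 at row {row}: the Weibull hazard is "
                "undefined at the time origin"
            )
        # strict nesting: each surgeon under exactly one center
        centers_per_surgeon = frame.groupby("surgeon")["center"].nunique()
        violated = centers_per_surgeon[centers_per_surgeon > 1]
        if len(violated):
            raise NestingError(
                f"surgeon {violated.index[0]!r} appears under "
                f"{int(violated.iloc[0])} centers; surgeons must be nested "
                "within a single center (disambiguate the labels or fix the "
                "data)"
            )

    @staticmethod
    def _drop_zero_time(frame: pd.DataFrame) -> pd.DataFrame:
        # censored records at t = 0 carry no likelihood information
        zero = (frame["time"] == 0) & (frame["event"] == 0)
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} censored record(s) with "
                "follow-up time 0 (no likelihood contribution)",
                stacklevel=3,
            )
            frame = frame[~zero].reset_index(drop=True)
        return frame

    # -- basic properties -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def n_centers(self) -> int:
        return len(self.center_ids)

    @property
    def n_surgeons(self) -> int:
        return len(self.surgeon_pairs)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def surgeon_code(self, surgeon_id, center_id=None) -> int:
        """Integer code of a surgeon, optionally disambiguated by center."""
        hits = [
            i
            for i, (c, s) in enumerate(self.surgeon_pairs)
            if s == surgeon_id and (center_id is None or c == center_id)
        ]
        if not hits:
            raise KeyError(f"unknown surgeon {surgeon_id!r}")
        if len(hits) > 1:
            raise KeyError(
                f"surgeon label {surgeon_id!r} is ambiguous; pass center_id"
            )
        return hits[0]

    def center_code(self, center_id) -> int:
        codes = {c: i for i, c in enumerate(self.center_ids)}
        if center_id not in codes:
            raise KeyError(f"unknown center {center_id!r}")
        return codes[center_id]

    # -- reporting --------------------------------------------------------

    def summarize(self) -> dict:
        """Hierarchy and follow-up summary.

        Returns a dict with ``n``, ``n_centers``, ``n_surgeons``, per-center
        surgeon counts ``J_k``, per-surgeon subject counts ``I_jk``, the
        overall event count/fraction and follow-up quantiles.
        """
        frame = self.frame
        J_k = {
            c: int(v)
            for c, v in frame.groupby("center")["surgeon"].nunique().items()
        }
        I_jk = {
            (c, s): int(v)
            for (c, s), v in frame.groupby(["center", "surgeon"]).size().items()
        }
        q = np.quantile(self.time, [0.0, 0.25, 0.5, 0.75, 1.0])
        return {
            "n": self.n,
            "n_centers": self.n_centers,
            "n_surgeons": self.n_surgeons,
            "surgeons_per_center": J_k,
            "subjects_per_surgeon": I_jk,
            "n_events": self.n_events,
            "event_fraction": self.n_events / self.n if self.n else float("nan"),
            "followup_quantiles": dict(zip(("min", "q25", "median", "q75", "max"), q)),
        }


def read_dataset(path, schema: Schema | None = None, delimiter: str | None = None) -> SurvivalDataset:
    """Read a delimited text file into a :class:`SurvivalDataset`.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV/TSV file with a header row.
    schema : Schema, optional
        Binds column names to roles.  When omitted, columns named ``time``,
        ``event``, ``surgeon`` and ``center`` are expected and every other
        column is treated as a covariate.
    delimiter : str, optional
        Field delimiter; sniffed from the file when omitted.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    if schema is None:
        missing = [c for c in ROLES if c not in df.columns]
        if missing:
            raise SchemaError(f"required column {missing[0]!r} is missing")
        covs = [c for c in df.columns if c not in ROLES]
        schema = Schema(covariates=covs)
    rename = {
        schema.time: "time",
        schema.event: "event",
        schema.surgeon: "surgeon",
        schema.center: "center",
    }
    for role, col in (("time", schema.time), ("event", schema.event),
                      ("surgeon", schema.surgeon), ("center", schema.center)):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} (role {role!r}) is missing")
    for cov in schema.covariates:
        if cov not in df.columns:
            raise SchemaError(f"covariate column {cov!r} is missing")
        vals = pd.to_numeric(df[cov], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(
                f"covariate {cov!r} is non-numeric or missing at row {row}"
            )
    out = df.rename(columns=rename)[["time", "event", "surgeon", "center"] + list(schema.covariates)]
    return SurvivalDataset(out, schema.covariates)


def write_dataset(dataset: SurvivalDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text (inverse of :func:`read_dataset`)."""
    cols = ["time", "event", "surgeon", "center"] + dataset.covariate_names
    dataset.frame[cols].to_csv(path, sep=delimiter, index=False)
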