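"""Reading survival datasets from delimited text, summaries and fixtures.

Input files carry one row per subject with a follow-up time column and a
status column (1 = event, 0 = censored).  The summary reports the
quantities a follow-up assessment starts from: censoring proportion, the
largest observed and largest uncensored times, and the number of censored
observations on the Kaplan-Meier plateau.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .simstudy import generate_sample, make_setting, uncured_quantile
from .survcore import SurvivalSample

__all__ = ["DatasetFile", "read_dataset", "summarize", "make_fixture"]

FIXTURE_KINDS = (
    "toy4",
    "toy3-events",
    "setting1-n50",
    "setting1-n250",
    "setting1-n500",
    "breast-synthetic",
)


@dataclass(frozen=True)
class DatasetFile:
    """A delimited text file with named time and status columns."""

    path: Path
    time_col: str = "time"
    status_col: str = "status"
    delimiter: str = ","

    def __post_init__(self):
        object.__setattr__(self, "path", Path(self.path))


def read_dataset(file: DatasetFile) -> SurvivalSample:
    """Parse and validate a survival dataset.

    Errors name the offending row (1-based, excluding the header) so a
    malformed export is easy to fix.
    """
    if not file.path.exists():
        raise InvalidInputError(f"no such file: {file.path}")
    sep = file.delimiter if file.delimiter != "whitespace" else r"\s+"
    frame = pd.read_csv(file.path, sep=sep)
    if frame.empty:
        raise InvalidInputError(f"{file.path}: no data rows")
    for col in (file.time_col, file.status_col):
        if col not in frame.columns:
            raise InvalidInputError(
                f"{file.path}: missing column {col!r} "
                f"(found {list(frame.columns)})"
            )
    times = pd.to_numeric(frame[file.time_col], errors="coerce")
    status = pd.to_numeric(frame[file.status_col], errors="coerce")
    bad = np.flatnonzero(times.isna() | (times < 0))
    if bad.size:
        raise InvalidInputError(
            f"{file.path}: non-numeric or negative time in row(s) "
            f"{[int(i) + 1 for i in bad[:10]]}"
        )
    bad = np.flatnonzero(~status.isin((0, 1)))
    if bad.size:
        raise InvalidInputError(
            f"{file.path}: status must be 0 or 1; offending row(s) "
            f"{[int(i) + 1 for i in bad[:10]]}"
        )
    return SurvivalSample(times=times.to_numpy(float),
                          events=status.to_numpy(int))


def summarize(sample: SurvivalSample) -> dict:
    """Input summary: sizes, censoring proportion and plateau count.

    The plateau count applies the half-open rule: censored observations
    with ``y_max_event < Y <= y_max`` (strictly after the last event,
    inclusive of the largest observation).
    """
    n = sample.n
    events = sample.n_events
    out = {
        "n": n,
        "events": events,
        "censoring_proportion": 1.0 - events / n,
        "y_max": sample.y_max,
        "plateau_rule": "censored with y_max_event < Y <= y_max",
    }
    if events:
        y_tilde = sample.y_max_event
        plateau = int(np.sum(
            (sample.events == 0)
            & (sample.times > y_tilde)
            & (sample.times <= sample.y_max)
        ))
        out["y_max_event"] = y_tilde
        out["plateau_censored"] = plateau
    else:
        out["y_max_event"] = None
        out["plateau_censored"] = int(np.sum(sample.events == 0))
    return out


def _write_csv(path: Path, times, events) -> DatasetFile:
    frame = pd.DataFrame({"time": times, "status": events})
    frame.to_csv(path, index=False)
    return DatasetFile(path=path)


def make_fixture(kind: str, seed: int, directory) -> DatasetFile:
    """Write a seeded CSV fixture and return its descriptor.

    ``toy*`` fixtures are the tiny hand-checkable samples used in the
    worked examples; ``setting1-n*`` are mixture-cure draws (p = 0.8,
    censoring mass 0.2 at the 99% uncured quantile); ``breast-synthetic``
    is a synthetic stand-in loosely shaped like an observational breast
    cancer study (months scale, long plateau) - synthetic data only, not
    the real study.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if kind == "toy4":
        return _write_csv(directory / "toy4.csv", [1, 2, 3, 4], [1, 1, 1, 0])
    if kind == "toy3-events":
        return _write_csv(directory / "toy3_events.csv", [1, 2, 3], [1, 1, 1])
    if kind.startswith("setting1-n"):
        n = int(kind.split("setting1-n")[1])
        spec = make_setting(1, p=0.8, delta_g=0.2)
        tau_g = uncured_quantile(spec, 0.99)
        sample = generate_sample(spec, tau_g, n=n, seed=seed)
        return _write_csv(directory / f"setting1_n{n}.csv",
                          sample.times, sample.events)
    if kind == "breast-synthetic":
        spec = make_setting(1, p=0.4, delta_g=0.1)
        rng = np.random.default_rng(seed)
        uncured = rng.uniform(size=286) < spec.p
        t = np.full(286, np.inf)
        t[uncured] = rng.exponential(30.0, size=int(uncured.sum()))
        c = np.minimum(rng.uniform(0, 190, size=286), 171.0)
        y = np.round(np.minimum(t, c)).clip(min=1)
        d = (t <= c).astype(int)
        return _write_csv(directory / "breast_synthetic.csv", y, d)
    raise InvalidInputError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
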