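"""Delimited-text interchange formats and configuration handling.

All intermediate artifacts are tab-separated text with a header row, optionally
preceded by ``#``-prefixed comment lines carrying provenance (notably the
configuration hash), so any pipeline stage can be rerun in isolation from the
previous stage's files.

Formats:
- medication records: subject_id, drug, time_s, event (rate|bolus), value
- intent periods:     subject_id, start_s, end_s
- epoch counts:       epoch_index, n_suppressed_samples, n_valid_samples
- BSP trajectories:   epoch, bsp, ci_lo, ci_hi, n, N
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from .bsp import BSPTrajectory, EpochCounts
from .records import MedicationRecord

Interval = tuple[float, float]


def _write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------- medications

def write_med_records(
    records: dict[str, MedicationRecord] | MedicationRecord,
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    if isinstance(records, MedicationRecord):
        records = {records.subject_id or "S01": records}
    rows = []
    for sid, rec in records.items():
        for drug, steps in rec.rates.items():
            for t, r in steps:
                rows.append((sid, drug, t, "rate", r))
        for drug, evts in rec.boluses.items():
            for t, d in evts:
                rows.append((sid, drug, t, "bolus", d))
    df = pd.DataFrame(rows, columns=["subject_id", "drug", "time_s", "event", "value"])
    df = df.sort_values(["subject_id", "drug", "time_s"], kind="stable")
    _write_table(df, path, header_lines)


def read_med_records(path: str | Path) -> dict[str, MedicationRecord]:
    """Parse a medication table into per-subject records.

    Rejects unknown event types and per-(subject, drug) time disorder, naming
    the offending line of the file.
    """
    path = Path(path)
    out: dict[str, MedicationRecord] = {}
    rates: dict[str, dict[str, list]] = {}
    boluses: dict[str, dict[str, list]] = {}
    last_t: dict[tuple[str, str, str], float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    header = None
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            expected = ["subject_id", "drug", "time_s", "event", "value"]
            if header != expected:
                raise ValueError(f"{path}:{lineno}: expected header {expected}, got {header}")
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        sid, drug, t_s, event, value = parts
        t, v = float(t_s), float(value)
        if event not in ("rate", "bolus"):
            raise ValueError(f"{path}:{lineno}: unknown event {event!r}")
        key = (sid, drug, event)
        if key in last_t and t < last_t[key]:
            raise ValueError(f"{path}:{lineno}: out-of-order time {t} for {sid}/{drug}")
        last_t[key] = t
        store = rates if event == "rate" else boluses
        store.setdefault(sid, {}).setdefault(drug, []).append((t, v))
    for sid in sorted(set(rates) | set(boluses)):
        out[sid] = MedicationRecord(rates.get(sid, {}), boluses.get(sid, {}), subject_id=sid)
    return out


# -------------------------------------------------------------- intent periods

def write_intent_periods(
    periods: dict[str, list[Interval]],
    path: str | Path,
    header_lines: list[str] | None = None,
) -> None:
    rows = [(sid, s, e) for sid, ivs in periods.items() for s, e in ivs]
    _write_table(pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s"]),
                 path, header_lines)


def read_intent_periods(path: str | Path) -> dict[str, list[Interval]]:
    df = read_table(path)
    out: dict[str, list[Interval]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject_id"]), []).append(
            (float(row["start_s"]), float(row["end_s"]))
        )
    return out


# ---------------------------------------------------------------- epoch counts

def write_epoch_counts(
    counts: EpochCounts, path: str | Path, header_lines: list[str] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(counts)),
            "n_suppressed_samples": counts.n,
            "n_valid_samples": counts.N,
        }
    )
    _write_table(df, path, header_lines)


def read_epoch_counts(path: str | Path, epoch_len: float = 1.0) -> EpochCounts:
    df = read_table(path)
    return EpochCounts(
        df["n_suppressed_samples"].to_numpy(),
        df["n_valid_samples"].to_numpy(),
        epoch_len,
    )


# ----------------------------------------------------------------- trajectories

def write_trajectory(
    traj: BSPTrajectory, path: str | Path, header_lines: list[str] | None = None
) -> None:
    n = traj.counts.n if traj.counts is not None else np.zeros(len(traj), int)
    N = traj.counts.N if traj.counts is not None else np.zeros(len(traj), int)
    df = pd.DataFrame(
        {
            "epoch": np.arange(len(traj)),
            "bsp": traj.bsp,
            "ci_lo": traj.ci_lo,
            "ci_hi": traj.ci_hi,
            "n": n,
            "N": N,
        }
    )
    _write_table(df, path, header_lines)


def read_trajectory(path: str | Path, epoch_len: float = 1.0) -> BSPTrajectory:
    """Rebuild a trajectory from its table; the logit-scale mode and variance are
    reconstructed from the stored BSP and upper credible bound."""
    df = read_table(path)
    p = np.clip(df["bsp"].to_numpy(), 1e-12, 1 - 1e-12)
    hi = np.clip(df["ci_hi"].to_numpy(), 1e-12, 1 - 1e-12)
    x = logit(p)
    sd = (logit(hi) - x) / 1.96
    counts = EpochCounts(df["n"].to_numpy(), df["N"].to_numpy(), epoch_len)
    return BSPTrajectory(x, sd**2, float("nan"), epoch_len, counts, kind="smoothed")


# -------------------------------------------------------------- configuration

def config_to_yaml(config_dict: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a flat configuration mapping."""
    import hashlib

    canon = "\n".join(f"{k}={config_dict[k]!r}" for k in sorted(config_dict))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
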