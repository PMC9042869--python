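"""File formats: subject tables, connectome matrices, reports, configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from plvcpm.connectivity import Connectome
from plvcpm.cpm import SCALE_RANGES
from plvcpm.synthetic import SubjectRecord
from plvcpm.validation import ValidationReport

SUBJECT_COLUMNS = ["subject_id", "score", "scale", "group", "age", "gender"]


class FormatError(ValueError):
    """Malformed input file."""


def read_subject_table(path) -> list[SubjectRecord]:
    """Read and validate the subject CSV (id, score, scale, group, age, gender)."""
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    dupes = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate subject_id(s) {dupes}")
    records = []
    for idx, row in df.iterrows():
        scale = str(row["scale"])
        if scale not in SCALE_RANGES:
            raise FormatError(f"{path} row {idx}: unknown scale {scale!r}")
        score = float(row["score"])
        if not 0 <= score <= SCALE_RANGES[scale]:
            raise FormatError(
                f"{path} row {idx}: score {score} outside {scale} range "
                f"[0, {SCALE_RANGES[scale]:.0f}]"
            )
        try:
            records.append(
                SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    raw_score=score,
                    scale=scale,
                    group=str(row["group"]),
                    age=float(row["age"]),
                    gender=int(row["gender"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path} row {idx}: {exc}") from exc
    return records


def write_subject_table(records: Iterable[SubjectRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "score": r.raw_score,
                "scale": r.scale,
                "group": r.group,
                "age": r.age,
                "gender": r.gender,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_connectome(path, expected_n: int = 68, band: str = "alpha", subject_id: str = "") -> Connectome:
    """Read a delimited square matrix and validate connectome invariants."""
    try:
        m = np.loadtxt(path)
    except ValueError as exc:
        raise FormatError(f"{path}: not a numeric matrix ({exc})") from exc
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{path}: matrix shape {m.shape} is not square")
    if expected_n and m.shape[0] != expected_n:
        raise FormatError(f"{path}: expected {expected_n}x{expected_n}, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise FormatError(f"{path}: matrix asymmetric beyond tolerance 1e-8")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    if m.min() < 0 or m.max() > 1:
        raise FormatError(f"{path}: entries outside [0, 1]")
    return Connectome(m, band=band, subject_id=subject_id or Path(path).stem)


def write_connectome(conn: Connectome, path) -> None:
    np.savetxt(path, conn.matrix, fmt="%.8f")


def load_edge_matrix(matrix_dir, records: list[SubjectRecord], expected_n: int = 68) -> np.ndarray:
    """Stack per-subject matrices (``<subject_id>.txt``) into subjects x edges."""
    matrix_dir = Path(matrix_dir)
    rows = []
    for rec in records:
        f = matrix_dir / f"{rec.subject_id}.txt"
        if not f.exists():
            raise FormatError(f"missing connectome file {f}")
        rows.append(read_connectome(f, expected_n=expected_n, subject_id=rec.subject_id).edge_vector())
    return np.vstack(rows)


def report_to_text(report: ValidationReport, title: str = "Validation report") -> str:
    """Aligned human-readable summary table."""
    lines = [title, "=" * len(title)]
    rows = [
        ("r", f"{report.r_mean:.3f} +/- {report.r_sd:.3f}"),
        ("MAE", f"{report.mae_mean:.3f} +/- {report.mae_sd:.3f}"),
        ("R-squared", f"{report.r2_mean:.3f} +/- {report.r2_sd:.3f}"),
        ("dummy MAE", f"{report.dummy_mae:.3f}"),
    ]
    if report.perm_p is not None:
        rows.append(("permutation p", f"{report.perm_p:.4f}"))
    if report.k:
        rows.append(("k / iterations", f"{report.k} / {report.n_iterations}"))
    if report.per_group:
        for g, m in report.per_group.items():
            rows.append((f"group {g} (n={m['n']})", f"r={m['r']:.3f}, MAE={m['mae']:.3f}"))
    width = max(len(name) for name, _ in rows)
    lines += [f"{name.ljust(width)}  {val}" for name, val in rows]
    return "\n".join(lines) + "\n"


def write_report(report: ValidationReport, path, config: dict | None = None) -> None:
    """Write a JSON report (with config echo) and a .txt summary beside it."""
    path = Path(path)
    payload = {"report": report.to_dict(), "config": config or {}}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    with open(path.with_suffix(".txt"), "w") as fh:
        fh.write(report_to_text(report))


def read_report(path) -> tuple[ValidationReport, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    d = payload["report"]
    return ValidationReport(**d), payload.get("config", {})
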