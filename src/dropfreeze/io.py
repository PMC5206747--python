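"""Readers, writers and run configuration.

Droplet CSV dialect (input):
    ``sample_id,treatment,plate_id,droplet_id,freeze_temp_c,censored``
with ``censored`` in {0, 1} and temperatures in decimal degC. One assay is
built per (sample_id, treatment) pair. Parsing is strict: malformed rows are
reported with their line number.

Spectrum TSV (output):
    ``temp_c,k_per_ml,ci_low,ci_high,n_unfrozen,n_total,censored``

Comparison TSV (output):
    ``sample_id,treatment,onset_c,onset_decrease_c,t50_c,delta_t50_c,
    k_m6,pct_m6,k_m8,pct_m8,k_m10,pct_m10,p_welch,p_boot``

Printed precision follows the field's table conventions: temperatures to
0.1 degC, concentrations to 0.1 IN/mL, percentages to whole percent.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .assay import TREATMENTS, AssaySummary, DropletAssay, DropletRecord, Spectrum

logger = logging.getLogger("dropfreeze")

__all__ = [
    "RunConfig",
    "CSV_COLUMNS",
    "read_droplet_csv",
    "write_droplet_csv",
    "write_spectrum_tsv",
    "write_summary_tsv",
    "write_truth_tsv",
    "load_run_config",
]

CSV_COLUMNS = ["sample_id", "treatment", "plate_id", "droplet_id", "freeze_temp_c", "censored"]


@dataclass
class RunConfig:
    """Configuration shared by the pipeline commands."""

    input_path: Path | None = None
    output_dir: Path = Path(".")
    grid_step: float = 0.2
    ref_temps: tuple[float, ...] = (-6.0, -8.0, -10.0)
    ci_level: float = 0.95
    n_resamples: int = 2000
    seed: int | None = None
    droplet_volume: float = 0.01
    control_label: str = "crude"

    def __post_init__(self) -> None:
        if any(t >= 0 for t in self.ref_temps):
            raise ValueError("ref_temps must be strictly negative")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("this operation is stochastic and requires a seed")
        return self.seed


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "input_path" in raw and raw["input_path"] is not None:
        raw["input_path"] = Path(raw["input_path"])
    if "output_dir" in raw:
        raw["output_dir"] = Path(raw["output_dir"])
    if "ref_temps" in raw:
        raw["ref_temps"] = tuple(float(t) for t in raw["ref_temps"])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# droplet CSV
# ---------------------------------------------------------------------------


def read_droplet_csv(
    path: str | Path, droplet_volume: float = 0.01, cooling_rate: float = 2.0
) -> list[DropletAssay]:
    """Strictly parse a droplet CSV into one assay per (sample, treatment)."""
    path = Path(path)
    groups: dict[tuple[str, str], list[DropletRecord]] = {}
    order: list[tuple[str, str]] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                temp = float(row["freeze_temp_c"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: non-numeric freeze_temp_c {row['freeze_temp_c']!r}"
                ) from None
            cen = row["censored"].strip()
            if cen not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: censored must be 0 or 1, got {cen!r}")
            censored = cen == "1"
            if not censored and temp > 0:
                raise ValueError(
                    f"{path}:{lineno}: freezing temperature {temp} degC is above 0"
                )
            trt = row["treatment"].strip()
            if trt not in TREATMENTS:
                raise ValueError(f"{path}:{lineno}: unknown treatment {trt!r}")
            key = (row["sample_id"].strip(), trt)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(
                DropletRecord(
                    plate_id=row["plate_id"].strip(),
                    droplet_id=row["droplet_id"].strip(),
                    freeze_temp=temp,
                    censored=censored,
                )
            )
    if not order:
        raise ValueError(f"{path}: no droplet rows")
    assays = []
    for sample_id, trt in order:
        assays.append(
            DropletAssay(
                sample_id=sample_id,
                treatment=trt,
                records=groups[(sample_id, trt)],
                droplet_volume=droplet_volume,
                cooling_rate=cooling_rate,
            )
        )
        logger.info(
            "read assay %s/%s: N0=%d, V=%.4f mL",
            sample_id, trt, len(groups[(sample_id, trt)]), droplet_volume,
        )
    return assays


def write_droplet_csv(assays: list[DropletAssay], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for assay in assays:
            for rec in assay.records:
                writer.writerow(
                    [
                        assay.sample_id,
                        assay.treatment,
                        rec.plate_id,
                        rec.droplet_id,
                        f"{rec.freeze_temp:.3f}",
                        int(rec.censored),
                    ]
                )


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------


def _fmt(x: float | None, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{nd}f}"


def write_spectrum_tsv(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["temp_c", "k_per_ml", "ci_low", "ci_high", "n_unfrozen", "n_total", "censored"])
        for j, t in enumerate(spectrum.grid):
            censored = int(spectrum.n_unfrozen[j] == 0)
            writer.writerow(
                [
                    _fmt(float(t), 1),
                    _fmt(float(spectrum.K[j]), 1),
                    _fmt(float(spectrum.ci_low[j]), 1),
                    _fmt(float(spectrum.ci_high[j]), 1),
                    int(spectrum.n_unfrozen[j]),
                    spectrum.n_total,
                    censored,
                ]
            )


def write_summary_tsv(summaries: list[AssaySummary], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", "treatment", "onset_c", "t50_c", "n_total", "n_frozen"])
        for s in summaries:
            writer.writerow(
                [s.sample_id, s.treatment, _fmt(s.onset_temp, 1), _fmt(s.t50, 1), s.n_total, s.n_frozen]
            )


def write_truth_tsv(grid: np.ndarray, lam: np.ndarray, k_target: np.ndarray, path: str | Path) -> None:
    """Closed-form scenario truth: Lambda(T) and the estimator target K_true(T)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["temp_c", "lambda_per_ml", "k_target_per_ml"])
        for t, l, k in zip(grid, lam, k_target):
            writer.writerow([_fmt(float(t), 1), f"{l:.6g}", f"{k:.6g}" if np.isfinite(k) else "inf"])
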