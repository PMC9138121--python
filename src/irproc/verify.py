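"""Pixelwise comparison of produced temperatures against reference exports.

Given a folder of temperature CSVs produced by the batch processor and a
folder of reference CSVs exported from other software, files are matched by
name stem and compared pixel by pixel over the cells defined in both grids.
The report lists the mean and maximum absolute difference per image and
overall, and a scatter plot (produced vs reference) is drawn per image.

Some manufacturer tools clamp their export at -40 degC; pixels where the
reference sits exactly on that floor while the produced value is colder are
counted separately rather than treated as disagreements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import flir_io
from .flir_io import FormatError
from .radiometry import TemperatureFrame

logger = logging.getLogger(__name__)

REFERENCE_FLOOR_C = -40.0


class VerifyError(Exception):
    pass


@dataclass
class ImageComparison:
    name: str
    n_pixels: int
    mean_abs_diff: float
    max_abs_diff: float
    n_skipped: int = 0
    n_floor: int = 0
    scatter_path: str | None = None
    error: str | None = None


@dataclass
class ComparisonReport:
    images: list[ImageComparison] = field(default_factory=list)

    @property
    def compared(self) -> list[ImageComparison]:
        return [c for c in self.images if c.error is None]

    @property
    def overall_mean(self) -> float:
        ok = self.compared
        total = sum(c.n_pixels for c in ok)
        return sum(c.mean_abs_diff * c.n_pixels for c in ok) / total if total else np.nan

    @property
    def overall_max(self) -> float:
        ok = self.compared
        return max((c.max_abs_diff for c in ok), default=np.nan)

    def to_text(self) -> str:
        lines = ["image,n_pixels,mean_abs_diff_C,max_abs_diff_C,skipped,floor_pixels"]
        for c in self.images:
            if c.error is not None:
                lines.append(f"{c.name},ERROR,{c.error}")
            else:
                lines.append(
                    f"{c.name},{c.n_pixels},{c.mean_abs_diff:.6f},{c.max_abs_diff:.6f},"
                    f"{c.n_skipped},{c.n_floor}"
                )
        lines.append(f"overall mean absolute difference (C): {self.overall_mean:.6f}")
        lines.append(f"overall maximum absolute difference (C): {self.overall_max:.6f}")
        return "\n".join(lines) + "\n"


def read_reference_csv(path: str | Path) -> TemperatureFrame:
    """Read a reference temperature grid, auto-detecting ``,`` vs ``;``
    separators (export dialects vary by software version)."""
    text = Path(path).read_text()
    # a semicolon-separated export uses the comma as decimal mark, so any
    # semicolon at all means the European dialect
    sep = ";" if ";" in text[:2048] else ","
    rows = []
    for line in text.splitlines():
        if not line.strip():
            continue
        toks = [t.strip().replace(",", ".") if sep == ";" else t for t in line.split(sep)]
        try:
            rows.append([float(t) if t not in ("", "NaN", "nan") else np.nan for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}: unparseable reference row: {line[:60]!r}") from exc
    if not rows:
        raise FormatError(f"{path}: empty reference CSV")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged reference rows")
    return TemperatureFrame(temp_C=np.array(rows))


def _scatter(prod: np.ndarray, ref: np.ndarray, name: str, out_dir: Path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(ref, prod, ".", ms=2, alpha=0.5)
    lo = float(min(ref.min(), prod.min()))
    hi = float(max(ref.max(), prod.max()))
    ax.plot([lo, hi], [lo, hi], "k-", lw=0.8)
    ax.set_xlabel("reference temperature (degC)")
    ax.set_ylabel("produced temperature (degC)")
    ax.set_title(name)
    out = out_dir / f"{name}.scatter.png"
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
    return str(out)


def compare_to_reference(
    produced_dir: str | Path,
    reference_dir: str | Path,
    out_dir: str | Path | None = None,
    scatter: bool = True,
) -> ComparisonReport:
    """Compare every produced CSV with the same-stem reference CSV.

    Differences are absolute values over pixels defined in both grids, so
    the comparison is symmetric in its two inputs.  Per-image dimension
    mismatches are recorded and do not stop the run; no matching pair at
    all is an error.
    """
    produced_dir = Path(produced_dir)
    reference_dir = Path(reference_dir)
    out = Path(out_dir) if out_dir is not None else produced_dir
    out.mkdir(parents=True, exist_ok=True)

    pairs = []
    for p in sorted(produced_dir.glob("*.csv")):
        for cand in (reference_dir / p.name, reference_dir / f"{p.stem}.csv"):
            if cand.exists():
                pairs.append((p, cand))
                break
    if not pairs:
        raise VerifyError(
            f"no produced/reference CSV pairs matched between {produced_dir} and {reference_dir}"
        )

    report = ComparisonReport()
    for prod_path, ref_path in pairs:
        name = prod_path.stem
        try:
            prod = flir_io.read_temperature_csv(prod_path)
            ref = read_reference_csv(ref_path)
            if prod.temp_C.shape != ref.temp_C.shape:
                raise VerifyError(
                    f"shape mismatch: produced {prod.temp_C.shape} vs reference "
                    f"{ref.temp_C.shape}"
                )
        except (VerifyError, FormatError) as exc:
            logger.error("%s: %s", name, exc)
            report.images.append(ImageComparison(name, 0, np.nan, np.nan, error=str(exc)))
            continue
        both = prod.defined_mask() & ref.defined_mask()
        floor = both & (ref.temp_C == REFERENCE_FLOOR_C) & (prod.temp_C < REFERENCE_FLOOR_C)
        use = both & ~floor
        n_skipped = int(np.count_nonzero(~both))
        p_vals = prod.temp_C[use]
        r_vals = ref.temp_C[use]
        diffs = np.abs(p_vals - r_vals)
        comp = ImageComparison(
            name=name,
            n_pixels=int(use.sum()),
            mean_abs_diff=float(diffs.mean()) if diffs.size else np.nan,
            max_abs_diff=float(diffs.max()) if diffs.size else np.nan,
            n_skipped=n_skipped,
            n_floor=int(floor.sum()),
        )
        if scatter and diffs.size:
            comp.scatter_path = _scatter(p_vals, r_vals, name, out)
        report.images.append(comp)

    (out / "comparison_report.txt").write_text(report.to_text())
    return report
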