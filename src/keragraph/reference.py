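"""Published per-cell-type measurements, as accession-gated regression targets.

The source study reports network metrics for three epithelial cell types
(MDCK: canine kidney, HaCaT: human keratinocyte, RPE: mouse retinal
pigment epithelium), each as mean ± SD over 10 cells.  Reproducing them
requires the deposited microscopy/segmentation data
(Dryad doi:10.5061/dryad.3xsj3txht), which this package does not bundle;
when a local copy of the deposit is available, :func:`regression_check`
runs the full pipeline over its snake files and compares each metric to
the published value within ± one SD.  Without the deposit the table
still serves as the documented reference.

Note: the published cell volumes (e.g. 4.65 µm³ for an MDCK cell) are
dimensionally implausible for whole cells and are stored verbatim only
for completeness; volumes should always be computed from stacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .filament_metrics import CellMetrics

__all__ = ["PUBLISHED", "PublishedValue", "compare_to_published", "regression_check"]


@dataclass(frozen=True)
class PublishedValue:
    mean: float
    sd: float
    units: str

    def within_sd(self, value: float) -> bool:
        return abs(value - self.mean) <= self.sd


PUBLISHED: dict[str, dict[str, PublishedValue]] = {
    "MDCK": {
        "mean_segment_length": PublishedValue(0.80, 0.04, "µm"),
        "total_length_mm": PublishedValue(1.63, 0.41, "mm"),
        "density": PublishedValue(355.24, 56.49, "µm/µm³"),
        "bending_ratio": PublishedValue(0.92, 0.09, ""),
        "mean_curvature": PublishedValue(2.54, 0.11, "µm⁻¹"),
        "thickness_curvature_pearson": PublishedValue(-0.10, 0.0, ""),
        "cell_volume": PublishedValue(4.65, 1.13, "µm³ (as printed)"),
    },
    "HaCaT": {
        "mean_segment_length": PublishedValue(0.83, 0.13, "µm"),
        "total_length_mm": PublishedValue(4.40, 1.53, "mm"),
        "density": PublishedValue(604.82, 304.20, "µm/µm³"),
        "bending_ratio": PublishedValue(0.92, 0.08, ""),
        "mean_curvature": PublishedValue(2.97, 0.72, "µm⁻¹"),
        "thickness_curvature_pearson": PublishedValue(0.08, 0.0, ""),
        "cell_volume": PublishedValue(9.16, 6.10, "µm³ (as printed)"),
    },
    "RPE": {
        "mean_segment_length": PublishedValue(0.88, 0.05, "µm"),
        "total_length_mm": PublishedValue(1.57, 0.48, "mm"),
        "density": PublishedValue(585.60, 63.97, "µm/µm³"),
        "bending_ratio": PublishedValue(0.90, 0.10, ""),
        "mean_curvature": PublishedValue(3.30, 0.15, "µm⁻¹"),
        "thickness_curvature_pearson": PublishedValue(0.14, 0.0, ""),
        "cell_volume": PublishedValue(2.73, 0.95, "µm³ (as printed)"),
    },
}

# apparent persistence length, reported jointly for all three cell types
PERSISTENCE_LENGTH_UM = PublishedValue(2.6, 0.5, "µm")


def compare_to_published(
    cell_type: str, metrics: CellMetrics
) -> dict[str, tuple[float, PublishedValue, bool]]:
    """Compare computed cell metrics to the published table.

    Returns metric → (computed value, published value, within ± SD).
    Only metrics present in both are compared.
    """
    ref = PUBLISHED[cell_type]
    out: dict[str, tuple[float, PublishedValue, bool]] = {}
    pairs = {
        "mean_segment_length": metrics.mean_segment_length,
        "total_length_mm": metrics.total_length_mm,
        "density": metrics.density,
    }
    for name, value in pairs.items():
        if value is None or name not in ref:
            continue
        pv = ref[name]
        out[name] = (value, pv, pv.within_sd(value))
    return out


def regression_check(
    deposit_dir: str | Path,
    cell_type: str,
    epsilon: float | None = None,
) -> dict[str, tuple[float, PublishedValue, bool]]:
    """Run the pipeline over a local copy of the deposited snake files.

    ``deposit_dir`` must contain snake files (``*.txt``) for cells of
    *cell_type*; each is converted to a network model, per-cell metrics
    are averaged and compared against the published mean ± SD.
    """
    from .filament_metrics import cell_totals
    from .models import GraphParams
    from .network_graph import build_network
    from .snake_io import read_snakes

    deposit_dir = Path(deposit_dir)
    files = sorted(deposit_dir.glob("*.txt"))
    if not files:
        raise FileNotFoundError(f"no snake files in {deposit_dir}")
    params = GraphParams(epsilon=epsilon)
    totals = []
    for f in files:
        model = build_network(read_snakes(f, "tsoax"), params, cell_id=f.stem)
        totals.append(cell_totals(model))
    n = len(totals)
    mean_metrics = CellMetrics(
        cell_id=f"{cell_type}-mean-of-{n}",
        n_segments=int(sum(t.n_segments for t in totals) / n),
        mean_segment_length=sum(t.mean_segment_length for t in totals) / n,
        total_length=sum(t.total_length for t in totals) / n,
        cell_volume=None,
        density=None,
        apparent_persistence_length=None,
        brightness_hist=totals[0].brightness_hist,
        brightness_bin_edges=totals[0].brightness_bin_edges,
        thickness_curvature_pearson=None,
    )
    return compare_to_published(cell_type, mean_metrics)
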