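"""End-to-end comparative analysis: the five-comparison report grid.

The canonical design regresses two responses (surface area, volume) of two
nasal regions on three size proxies, in five proxy-by-region comparisons:

1. whole nasal cavity   vs body mass
2. whole nasal cavity   vs skull volume
3. whole nasal cavity   vs convex-hull head-model volume
4. respiratory region   vs skull volume
5. respiratory region   vs head-model volume

each fitted by OLS, SMA and PGLS with the conditional slope-then-intercept
test.  Mammals are excluded from respiratory-region comparisons: their
turbinates offer no landmark to split the olfactory from the respiratory
region, so the region label does not exist for them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allometry import AllometricFit
from .comparisons import GroupComparisonResult, compare_groups
from .io import load_measurements
from .phylo import bm_covariance, expand_conspecific_tips
from .reconstruct import FossilPlacement, place_fossil

__all__ = [
    "AnalysisConfig",
    "COMPARISONS",
    "ComparisonReport",
    "TreeReconciliationError",
    "estimate_crocodylian_mass",
    "export_report",
    "run_full_analysis",
]

# (comparison id, size proxy column, region)
COMPARISONS = [
    ("nasal_vs_body_mass", "body_mass_g", "nasal"),
    ("nasal_vs_skull_vol", "skull_vol_mm3", "nasal"),
    ("nasal_vs_hull_vol", "hull_vol_mm3", "nasal"),
    ("resp_vs_skull_vol", "skull_vol_mm3", "resp"),
    ("resp_vs_hull_vol", "hull_vol_mm3", "resp"),
]

_RESPONSE_COLUMNS = {
    ("nasal", "surface_area"): "nasal_sa_mm2",
    ("nasal", "volume"): "nasal_vol_mm3",
    ("resp", "surface_area"): "resp_sa_mm2",
    ("resp", "volume"): "resp_vol_mm3",
}


class TreeReconciliationError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """What to compute: comparisons, responses, methods, exclusions."""

    comparisons: list[str] = field(default_factory=lambda: [c[0] for c in COMPARISONS])
    responses: list[str] = field(default_factory=lambda: ["surface_area", "volume"])
    methods: list[str] = field(default_factory=lambda: ["ols", "sma", "pgls"])
    alpha: float = 0.05
    respiratory_excluded_clades: list[str] = field(default_factory=lambda: ["Mammalia"])
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        known = {c[0] for c in COMPARISONS}
        unknown = set(self.comparisons) - known
        if unknown:
            raise ValueError(f"unknown comparisons: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "comparisons": list(self.comparisons),
            "responses": list(self.responses),
            "methods": list(self.methods),
            "alpha": self.alpha,
            "respiratory_excluded_clades": list(self.respiratory_excluded_clades),
            "seed": self.seed,
        }


@dataclass
class ComparisonReport:
    """Grid of comparison results plus fitted lines and fossil placements."""

    config: AnalysisConfig
    cells: dict[tuple[str, str, str], GroupComparisonResult]
    fossil_placements: dict[str, FossilPlacement] = field(default_factory=dict)

    def cell(self, comparison: str, response: str, method: str) -> GroupComparisonResult:
        return self.cells[(comparison, response, method)]

    def fitted_line_table(self) -> pd.DataFrame:
        rows = []
        for (comp, resp, method), res in sorted(self.cells.items()):
            for group, fit in res.fits.items():
                rows.append(
                    {
                        "comparison": comp,
                        "response": resp,
                        "method": method,
                        "group": group,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "n": fit.n,
                        "r2": fit.r2,
                    }
                )
        return pd.DataFrame(rows)

    def summary_table(self) -> pd.DataFrame:
        """Report grid: one row per comparison x response, p-values per method."""
        order = {c: i for i, (c, _, _) in enumerate(COMPARISONS)}
        keys = sorted(self.cells, key=lambda k: (order.get(k[0], 99), k[1], k[2]))
        rows: dict[tuple[str, str], dict] = {}
        for comp, resp, method in keys:
            res = self.cells[(comp, resp, method)]
            row = rows.setdefault((comp, resp), {"comparison": comp, "response": resp})
            row[f"{method}_slope_p"] = res.slope_p
            row[f"{method}_intercept_p"] = res.intercept_p if res.intercept_tested else "—"
        return pd.DataFrame(list(rows.values()))

    def to_json(self) -> str:
        payload = {
            "config": self.config.to_dict(),
            "cells": [
                {"key": list(key), **res.to_dict()} for key, res in sorted(self.cells.items())
            ],
            "fossil_placements": {k: v.to_dict() for k, v in self.fossil_placements.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        payload = json.loads(text)
        config = AnalysisConfig(**payload["config"])
        cells = {}
        for entry in payload["cells"]:
            key = tuple(entry.pop("key"))
            cells[key] = GroupComparisonResult.from_dict(entry)
        placements = {
            k: FossilPlacement(
                x=v["x"],
                y_bony=v["y_bony"],
                y_corrected_range=tuple(v["y_corrected_range"]),
                predicted_endo=v["predicted_endo"],
                predicted_ecto=v["predicted_ecto"],
                relative_index_bony=v["relative_index_bony"],
                relative_index_corrected=tuple(v["relative_index_corrected"]),
                prediction_se=v.get("prediction_se", {}),
            )
            for k, v in payload.get("fossil_placements", {}).items()
        }
        return cls(config=config, cells=cells, fossil_placements=placements)


def estimate_crocodylian_mass(length: float, coefficients: dict, equation_id: str) -> float:
    """Body mass (g) from a length measure via a configured power law.

    ``coefficients`` maps equation ids to ``{"a": ..., "b": ...}`` with
    mass = a * length**b; the coefficients are configuration values because
    published crocodylian equations differ in length measure and units.
    """
    if equation_id not in coefficients:
        raise KeyError(f"no coefficients configured for equation {equation_id!r}")
    eq = coefficients[equation_id]
    if "a" not in eq or "b" not in eq:
        raise KeyError(f"equation {equation_id!r} must define 'a' and 'b'")
    if length <= 0:
        raise ValueError("length must be positive")
    return float(eq["a"]) * float(length) ** float(eq["b"])


def _prepare_tree(records: pd.DataFrame, tree):
    """Expand conspecific tips and check every record resolves to a tip."""
    counts = records.groupby("species")["specimen_id"].apply(list).to_dict()
    species_on_tree = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(set(counts) - species_on_tree)
    if missing:
        raise TreeReconciliationError(f"species missing from tree: {missing}")
    multi = {sp: sids for sp, sids in counts.items() if len(sids) > 1}
    expanded = expand_conspecific_tips(tree, multi) if multi else tree
    tip_label = records.apply(
        lambda r: r["specimen_id"] if r["species"] in multi else r["species"], axis=1
    )
    return expanded, tip_label


def run_full_analysis(
    config: AnalysisConfig,
    records: pd.DataFrame | str | Path,
    tree=None,
    fossil: dict | None = None,
) -> ComparisonReport:
    """Run every requested comparison cell and assemble the report.

    *records* may be a DataFrame or a CSV path.  A tree is required when
    PGLS is among the methods.  *fossil* optionally supplies
    ``{"skull_vol_mm3": ..., "hull_vol_mm3": ..., "airway_vol_mm3": ...}``
    (raw mm^3) to place against the respiratory-volume PGLS lines.
    """
    if not isinstance(records, pd.DataFrame):
        records = load_measurements(records)
    need_pgls = "pgls" in [m.lower() for m in config.methods]
    C_full = labels_full = expanded = tip_label = None
    if need_pgls:
        if tree is None:
            raise ValueError("PGLS requested but no tree supplied")
        expanded, tip_label = _prepare_tree(records, tree)
        records = records.assign(tip_label=tip_label)
        C_full, labels_full = bm_covariance(expanded, taxa=records["tip_label"].tolist())
    comp_map = {c[0]: c for c in COMPARISONS}
    cells = {}
    for comp_id in config.comparisons:
        _, proxy, region = comp_map[comp_id]
        for response in config.responses:
            resp_col = _RESPONSE_COLUMNS[(region, response)]
            subset = records.dropna(subset=[proxy, resp_col])
            if region == "resp" and config.respiratory_excluded_clades:
                subset = subset[~subset["clade"].isin(config.respiratory_excluded_clades)]
            for method in config.methods:
                method = method.lower()
                C = None
                if method == "pgls":
                    idx = [records.index.get_loc(i) for i in subset.index]
                    C = C_full[np.ix_(idx, idx)]
                cells[(comp_id, response, method)] = compare_groups(
                    subset,
                    proxy,
                    resp_col,
                    method=method,
                    C=C,
                    alpha=config.alpha,
                    comparison=comp_id,
                )
    report = ComparisonReport(config=config, cells=cells)
    if fossil is not None:
        for comp_id, proxy in (("resp_vs_skull_vol", "skull_vol_mm3"), ("resp_vs_hull_vol", "hull_vol_mm3")):
            key = (comp_id, "volume", "pgls")
            if key not in cells or proxy not in fossil:
                continue
            res = cells[key]
            fit_endo = res.fits.get("endotherm")
            fit_ecto = res.fits.get("ectotherm")
            if fit_endo is None or fit_ecto is None:
                continue
            x = float(np.log10(fossil[proxy]))
            y = float(np.log10(fossil["airway_vol_mm3"]))
            report.fossil_placements[comp_id] = place_fossil(x, y, fit_endo, fit_ecto)
    return report


def export_report(report: ComparisonReport, out_dir: str | Path, formats=("csv", "json")) -> list[Path]:
    """Write the report grid; untested intercept cells appear as an em dash."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        path = out_dir / "comparison_report.csv"
        report.summary_table().to_csv(path, index=False)
        written.append(path)
        lines = out_dir / "fitted_lines.csv"
        report.fitted_line_table().to_csv(lines, index=False)
        written.append(lines)
    if "json" in formats:
        path = out_dir / "comparison_report.json"
        path.write_text(report.to_json())
        written.append(path)
    return written
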