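"""End-to-end orchestration: score, bin, correct, correlate, compare, summarise.

``run_full_analysis`` ties every stage together and writes a reproducible
report bundle: the per-bin mean CCM2 series, taxic and residual diversity,
the correlation battery, group comparisons, geographic summaries and a run
manifest.  Outputs are pure functions of (inputs, config); the manifest
records versions, the seedless config hash and file paths so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ccm import ENVIRONMENTS, score_all_species
from .chrono import (
    BinSeries,
    TimeBinTable,
    assign_occurrences,
    bin_assignment_mapping,
    make_substage_bins,
    mean_ccm2_series,
    species_incidence,
    taxic_diversity_series,
)
from .diversity import residual_diversity
from .errors import FossilCompError
from .geo import group_summary, latitudinal_summary
from .io import (
    load_contribution_table,
    read_bin_series,
    read_occurrences,
    read_stage_boundaries,
)
from .stats import gd_correlate, mann_whitney

logger = logging.getLogger("fossilcomp")

#: Stages making up the Late Cretaceous subset used in clade comparisons.
LATE_CRETACEOUS_STAGES = (
    "cenomanian", "turonian", "coniacian", "santonian", "campanian", "maastrichtian",
)


@dataclass
class PipelineConfig:
    """Paths and options of a full analysis run."""

    contribution_table: str
    occurrences: str
    stage_boundaries: str
    proxy: str | None = None
    sea_level: str | None = None
    comparison_ccm2: str | None = None
    per_bin: bool = True
    k_sd: float = 1.0
    gd: bool = True
    latitude_bin_width: float = 5.0
    mode: str = "count"
    display_ndigits: int = 2

    def __post_init__(self) -> None:
        if self.k_sd < 0:
            raise ValueError("k_sd must be non-negative")
        if self.mode not in ("count", "rounded_sum"):
            raise ValueError("mode must be 'count' or 'rounded_sum'")
        if not 0 < self.latitude_bin_width <= 90:
            raise ValueError("latitude_bin_width must lie in (0, 90]")
        for name in ("contribution_table", "occurrences", "stage_boundaries"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("proxy", "sea_level", "comparison_ccm2"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        base = Path(path).parent
        for key in ("contribution_table", "occurrences", "stage_boundaries",
                    "proxy", "sea_level", "comparison_ccm2"):
            if data.get(key):
                data[key] = str((base / data[key]).resolve())
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, FossilCompError):
                return False
            if exc is not None:
                raise FossilCompError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_full_analysis(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every analysis stage and write the report bundle to *outdir*.

    Returns the in-memory results: bin series, RDE, correlation and
    comparison tables, and the geographic summaries.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load inputs"):
        table = load_contribution_table(config.contribution_table)
        records = read_occurrences(config.occurrences)
        bins = TimeBinTable(make_substage_bins(read_stage_boundaries(config.stage_boundaries)).bins)
        proxy = read_bin_series(config.proxy) if config.proxy else None
        sea_level = read_bin_series(config.sea_level) if config.sea_level else None
        comparison = read_bin_series(config.comparison_ccm2) if config.comparison_ccm2 else None

    with _stage("assign occurrences to bins"):
        spec_inc = assign_occurrences(records, bins)
        sp_inc = species_incidence(records, spec_inc)
        assignment = bin_assignment_mapping(spec_inc)

    with _stage("score species CCM2"):
        pooled_scores = score_all_species(records, table, per_bin=False, mode=config.mode)
        per_bin_scores = score_all_species(
            records, table, per_bin=True, bin_assignment=assignment, mode=config.mode
        )

    with _stage("per-bin series"):
        ccm2_series = mean_ccm2_series(per_bin_scores, bins, spec_inc)
        taxic = taxic_diversity_series(sp_inc, bins)

    results: dict = {
        "bins": bins,
        "species_scores": pooled_scores,
        "mean_ccm2": ccm2_series,
        "taxic_diversity": taxic,
    }
    times = bins.midpoints()

    rde = None
    if proxy is not None:
        with _stage("residual diversity"):
            rde = residual_diversity(taxic, proxy, k_sd=config.k_sd)
            results["rde"] = rde

    with _stage("fluviolacustrine specimen counts"):
        fluvio_ids = [r.specimen_id for r in records if r.environment == "fluviolacustrine"]
        fluvio_counts = (
            spec_inc.loc[fluvio_ids].sum(axis=0).to_numpy(float)
            if fluvio_ids
            else np.zeros(len(bins))
        )
        fluvio_series = BinSeries(bins.labels, fluvio_counts, None, fluvio_counts.astype(int))
        results["fluviolacustrine_counts"] = fluvio_series

    with _stage("correlation battery"):
        pairs = [("mean_ccm2 vs taxic_diversity", ccm2_series.value, taxic.value)]
        if rde is not None:
            pairs.append(("mean_ccm2 vs residual_diversity", ccm2_series.value, rde.residual))
            pairs.append(("taxic_diversity vs proxy", taxic.value, proxy.value))
        pairs.append(
            ("mean_ccm2 vs fluviolacustrine_counts", ccm2_series.value, fluvio_series.value)
        )
        if sea_level is not None:
            pairs.append(("mean_ccm2 vs sea_level", ccm2_series.value, sea_level.value))
        if comparison is not None:
            pairs.append(("mean_ccm2 vs comparison_clade_ccm2", ccm2_series.value, comparison.value))
        corr_rows = []
        for name, x, y in pairs:
            for method in ("spearman", "kendall"):
                try:
                    res = gd_correlate(x, y, times, method=method, gd=config.gd)
                    corr_rows.append(
                        {"comparison": name, "method": method,
                         "statistic": res.statistic, "p_value": res.p_value, "n": res.n}
                    )
                except FossilCompError as exc:
                    logger.warning("correlation %s (%s) skipped: %s", name, method, exc)
        correlations = pd.DataFrame(
            corr_rows, columns=["comparison", "method", "statistic", "p_value", "n"]
        )
        results["correlations"] = correlations

    with _stage("group comparisons"):
        env_summary = group_summary(records, pooled_scores, grouping="environment")
        land_summary = group_summary(records, pooled_scores, grouping="landmass")
        mw_rows = []
        env_pairs = [
            ("fluviolacustrine", "other_terrestrial"),
            ("fluviolacustrine", "marine"),
            ("marine", "other_terrestrial"),
        ]
        for g1, g2 in env_pairs:
            s1 = env_summary.scores.get(g1, [])
            s2 = env_summary.scores.get(g2, [])
            if s1 and s2:
                res = mann_whitney(s1, s2)
                mw_rows.append(
                    {"comparison": f"{g1} vs {g2}", "u_statistic": res.u_statistic,
                     "p_value": res.p_value, "n1": res.n1, "n2": res.n2, "method": res.method}
                )
        if comparison is not None:
            own = ccm2_series.value[~np.isnan(ccm2_series.value)]
            other = comparison.value[~np.isnan(comparison.value)]
            if own.size and other.size:
                res = mann_whitney(own, other)
                mw_rows.append(
                    {"comparison": "mean_ccm2 vs comparison_clade (all bins)",
                     "u_statistic": res.u_statistic, "p_value": res.p_value,
                     "n1": res.n1, "n2": res.n2, "method": res.method}
                )
            lk_mask = np.array(
                [b.stage.lower() in LATE_CRETACEOUS_STAGES for b in bins.bins]
            )
            if lk_mask.any():
                own_lk = ccm2_series.value[lk_mask]
                other_lk = comparison.value[lk_mask]
                own_lk = own_lk[~np.isnan(own_lk)]
                other_lk = other_lk[~np.isnan(other_lk)]
                if own_lk.size and other_lk.size:
                    res = mann_whitney(own_lk, other_lk)
                    mw_rows.append(
                        {"comparison": "mean_ccm2 vs comparison_clade (Late Cretaceous)",
                         "u_statistic": res.u_statistic, "p_value": res.p_value,
                         "n1": res.n1, "n2": res.n2, "method": res.method}
                    )
        comparisons = pd.DataFrame(
            mw_rows, columns=["comparison", "u_statistic", "p_value", "n1", "n2", "method"]
        )
        results["environment_summary"] = env_summary
        results["landmass_summary"] = land_summary
        results["comparisons"] = comparisons

    with _stage("geographic summaries"):
        latitude = latitudinal_summary(records, pooled_scores, width=config.latitude_bin_width)
        results["latitude_summary"] = latitude

    with _stage("write outputs"):
        ccm2_series.to_frame().to_csv(outdir / "mean_ccm2.csv", index=False)
        taxic.to_frame().to_csv(outdir / "taxic_diversity.csv", index=False)
        if rde is not None:
            rde.to_frame().to_csv(outdir / "residual_diversity.csv", index=False)
        correlations.to_csv(outdir / "correlations.csv", index=False)
        comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
        env_summary.to_frame().to_csv(outdir / "environment_summary.csv", index=False)
        land_summary.to_frame().to_csv(outdir / "landmass_summary.csv", index=False)
        latitude.to_csv(outdir / "latitude_summary.csv", index=False)
        pd.DataFrame(
            {
                "species": list(pooled_scores),
                "ccm2": [s.value_percent for s in pooled_scores.values()],
            }
        ).sort_values("species").to_csv(outdir / "species_scores.csv", index=False)
        manifest = {
            "fossilcomp_version": __version__,
            "python_version": sys.version.split()[0],
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "n_specimens": len(records),
            "n_species": len(pooled_scores),
            "n_bins": len(bins),
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    return results
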