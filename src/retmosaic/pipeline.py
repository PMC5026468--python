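"""End-to-end pipeline: inputs → per-image metrics → retinal means → stats.

A run is described by a plain config mapping (loadable from TOML), executes
deterministically under its seed, and writes per-image metrics, per-retina
group tables, statistics reports, and a manifest tracing every output back
to inputs, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .drp import compute_drp
from .io import PointPattern, read_points_table, write_results
from .nn import nnri_ratio
from .stats import anova_tukey, retina_means, t_test
from .synth import gen_clustered, gen_dmin, gen_random
from .voronoi import compute_domains

logger = logging.getLogger(__name__)

__all__ = ["DEMO_CONFIG", "simulate_cohorts", "analyze_patterns", "run_pipeline"]

#: Reproducible demo: a mosaically spaced "wild-type" cohort (sequential
#: inhibition) against a clustered "mutant" cohort, 6 retinas x 3 images each.
DEMO_CONFIG = {
    "mode": "demo",
    "seed": 0,
    "window": [0.0, 0.0, 1000.0, 1000.0],
    "n_retinas": 6,
    "images_per_retina": 3,
    "cohorts": {
        "wild-type": {"kind": "dmin", "n": 300, "dmin": 35.0},
        "mutant": {"kind": "clustered", "n_parents": 60, "offspring_mean": 5.0,
                   "cluster_sd": 12.0},
    },
    "drp": {"bin_width": 5.0, "max_radius": 200.0},
    "nnri_reps": 20,
}


def simulate_cohorts(config: dict, seed: int) -> list[PointPattern]:
    """Generate the demo cohorts: per-genotype regime, per-retina images."""
    window = tuple(config["window"])
    rng = np.random.default_rng(seed)
    patterns = []
    for genotype, spec in config["cohorts"].items():
        for r in range(config["n_retinas"]):
            retina = f"{genotype}-ret{r}"
            for i in range(config["images_per_retina"]):
                meta = dict(image_id=f"{retina}-img{i}", retina_id=retina,
                            genotype=genotype)
                kind = spec["kind"]
                # cell counts vary between fields of a real retina
                if kind == "dmin":
                    p = gen_dmin(int(rng.poisson(spec["n"])), window, spec["dmin"],
                                 seed=rng, **meta)
                elif kind == "random":
                    p = gen_random(int(rng.poisson(spec["n"])), window, seed=rng,
                                   **meta)
                elif kind == "clustered":
                    p = gen_clustered(spec["n_parents"], spec["offspring_mean"],
                                      spec["cluster_sd"], window, seed=rng, **meta)
                else:
                    raise ValueError(f"unknown cohort kind {kind!r}")
                patterns.append(p)
    return patterns


def analyze_patterns(
    patterns: list[PointPattern],
    seed: int = 0,
    bin_width: float | None = None,
    max_radius: float | None = None,
    nnri_reps: int = 99,
) -> pd.DataFrame:
    """Per-image spacing metrics: packing factor, Voronoi VMR, NNRI ratio."""
    rows = []
    for k, p in enumerate(patterns):
        drp = compute_drp(p, bin_width=bin_width, max_radius=max_radius)
        vor = compute_domains(p)
        nn = nnri_ratio(p, n_reps=nnri_reps, seed=seed + k)
        rows.append(
            {
                "image_id": p.image_id,
                "retina_id": p.retina_id,
                "genotype": p.genotype,
                "n_cells": p.n,
                "density": p.n / p.window_area,
                "packing_factor": drp.packing_factor,
                "effective_radius": drp.effective_radius,
                "voronoi_vmr": vor.vmr,
                "voronoi_cv2": vor.cv2,
                "nnri_ratio": nn.nnri_ratio,
            }
        )
    return pd.DataFrame(rows)


_METRICS = ("packing_factor", "voronoi_vmr", "nnri_ratio", "density")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute a full run and write results + manifest into ``out_dir``.

    Returns the manifest.  Modes: ``demo`` (synthetic cohorts per
    ``DEMO_CONFIG``-style keys) or ``points`` (read coordinate tables from
    ``config['inputs']`` with optional ``scale`` and ``metadata``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    digests = {}

    stage = "input"
    try:
        if config.get("mode", "demo") == "demo":
            patterns = simulate_cohorts(config, seed)
        else:
            patterns = []
            metadata = config.get("metadata", {})
            for path in config["inputs"]:
                if not Path(path).exists():
                    raise FileNotFoundError(f"input not found: {path}")
                digests[str(path)] = hashlib.sha256(
                    Path(path).read_bytes()
                ).hexdigest()
                patterns.extend(
                    read_points_table(path, scale=config.get("scale", 1.0),
                                      metadata=metadata)
                )

        stage = "per-image metrics"
        drp_cfg = config.get("drp", {})
        per_image = analyze_patterns(
            patterns,
            seed=seed,
            bin_width=drp_cfg.get("bin_width"),
            max_radius=drp_cfg.get("max_radius"),
            nnri_reps=int(config.get("nnri_reps", 99)),
        )
        write_results(per_image, out / "per_image_metrics.csv")

        stage = "retinal means"
        tables = {}
        for metric in _METRICS:
            cols = per_image[["image_id", "retina_id", "genotype", metric]].rename(
                columns={metric: "value"}
            )
            tables[metric] = retina_means(cols, metric_name=metric)
        combined = pd.concat(tables.values(), ignore_index=True)
        write_results(combined, out / "retina_means.csv")

        stage = "statistics"
        reports = []
        n_genotypes = combined["genotype"].nunique()
        for metric, table in tables.items():
            if n_genotypes == 2:
                reports.append((metric, t_test(table)))
            else:
                reports.extend((metric, r) for r in anova_tukey(table))
        stats_df = pd.DataFrame(
            [{"metric": m, **dataclasses.asdict(r)} for m, r in reports]
        )
        stats_df["groups"] = stats_df["groups"].map(lambda g: "|".join(g))
        stats_df["n_per_group"] = stats_df["n_per_group"].map(
            lambda n: "|".join(map(str, n))
        )
        write_results(stats_df, out / "stats_report.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}: {exc}") from exc

    manifest = {
        "package": "retmosaic",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_digests": digests,
        "n_images": len(patterns),
        "outputs": ["per_image_metrics.csv", "retina_means.csv", "stats_report.csv"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    logger.info("pipeline complete: %d images -> %s", len(patterns), out)
    return manifest
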