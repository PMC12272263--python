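"""End-to-end orchestration: surface -> fields -> fMRI -> connectivity ->
assignment -> EFSI -> summaries.

Each stage is an in-memory function; :func:`run_pipeline` composes them and
writes every artifact with lossless float formatting, so running the stage
CLI commands by hand against the written artifacts reproduces the pipeline
outputs exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assignment import (
    TargetingResult,
    assign_network,
    orientation_window,
    overlap_profile,
    results_frame,
    sparsify,
    summarize,
    zone_of,
)
from .config import RunConfig
from .connectivity import (
    ConnectivityMap,
    extract_seed,
    make_covariate,
    partial_corr_map,
    weighted_timeseries,
)
from .efield import (
    CoilModel,
    CoilPlacement,
    EFieldMap,
    build_grid,
    efsi,
    per_map_suprathreshold_fraction,
    primary_efield,
)
from .errors import InputError
from .fmri import TimeSeriesMatrix, simulate_rfmri
from .io import (
    FLOAT_FMT,
    write_parcellation,
    write_ply,
    write_timeseries,
    write_vertex_metric,
)
from .surface import ParcellationMap, SurfaceMesh, make_folded_sheet, make_parcellation

logger = logging.getLogger("tmsnet")

__all__ = [
    "run_pipeline",
    "stage_surface",
    "stage_fields",
    "stage_fmri",
    "stage_connectivity",
    "stage_assign",
    "placement_key",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_placements",
    "read_placements",
]


def placement_key(row: int, col: int, theta: int) -> str:
    return f"r{row}c{col}t{theta}"


def parse_placement_key(key: str) -> tuple[int, int, int]:
    try:
        r, rest = key[1:].split("c")
        c, t = rest.split("t")
        return int(r), int(c), int(t)
    except ValueError as exc:  # pragma: no cover - malformed external input
        raise InputError(f"malformed placement key {key!r}") from exc


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_surface(config: RunConfig) -> tuple[SurfaceMesh, ParcellationMap]:
    mesh = make_folded_sheet(
        config.profile(), config.resolution_value(), config.stage_seed("mesh")
    )
    parc = make_parcellation(
        mesh, config.layout_name(), config.stage_seed("parcellation")
    )
    logger.info(
        "surface: %d vertices, %d faces, %d labeled",
        mesh.n_vertices, mesh.n_faces, int((parc.labels > 0).sum()),
    )
    return mesh, parc


def stage_fields(
    config: RunConfig, mesh: SurfaceMesh
) -> tuple[list[CoilPlacement], list[EFieldMap]]:
    coil = CoilModel(
        radius_mm=config.coil_radius_mm,
        segments_per_loop=config.coil_segments_per_loop,
        di_dt=config.coil_di_dt,
    )
    placements = build_grid(config.profile(), mesh)
    fields = [primary_efield(coil, p, mesh) for p in placements]
    logger.info("fields: %d placements simulated", len(placements))
    return placements, fields


def stage_fmri(config: RunConfig, parc: ParcellationMap) -> TimeSeriesMatrix:
    t, tr = config.run_length()
    ts = simulate_rfmri(parc, config.signal_model(), t, tr, config.stage_seed("fmri"))
    logger.info("fmri: %d vertices x %d timepoints (TR %.3g s)", *ts.data.shape, tr)
    return ts


def stage_connectivity(
    config: RunConfig, fields: list[EFieldMap], ts: TimeSeriesMatrix
) -> tuple[list[ConnectivityMap], np.ndarray, np.ndarray]:
    """Seed extraction, grand-mean covariate, and one partial-correlation map
    per field.  Returns (maps, seed_series matrix (P, T), covariate)."""
    seeds = [
        extract_seed(f, config.seed_fraction, config.seed_normalization)
        for f in fields
    ]
    seed_series = np.stack([weighted_timeseries(s, ts) for s in seeds])
    covariate = make_covariate(list(seed_series))
    maps = [partial_corr_map(s, ts, covariate) for s in seed_series]
    logger.info(
        "connectivity: %d maps, median seed size %d",
        len(maps), int(np.median([s.size for s in seeds])),
    )
    return maps, seed_series, covariate


def stage_assign(
    config: RunConfig,
    maps: list[ConnectivityMap],
    placements: list[CoilPlacement],
    parc: ParcellationMap,
) -> list[TargetingResult]:
    results = []
    for p, conn in zip(placements, maps):
        binary = sparsify(conn, config.sparsity, config.rank_absolute)
        profile = overlap_profile(binary, parc, config.overlap_metric)
        network, tied = assign_network(profile)
        results.append(
            TargetingResult(
                row=p.row,
                col=p.col,
                theta_deg=p.theta_deg,
                profile=profile,
                network=network,
                tied=tied,
                zone=zone_of(p.row, p.col),
                window=orientation_window(p.theta_deg),
            )
        )
    logger.info("assign: %d targeting results", len(results))
    return results


# ---------------------------------------------------------------------------
# artifact I/O
# ---------------------------------------------------------------------------

def write_matrix_tsv(
    values: np.ndarray, columns: list[str], path: str | Path
) -> None:
    """Vertex x placement matrix with a vertex_index column (lossless floats)."""
    with open(path, "w") as fh:
        fh.write("vertex_index\t" + "\t".join(columns) + "\n")
        for i, row in enumerate(values):
            fh.write(str(i) + "\t" + "\t".join(FLOAT_FMT % x for x in row) + "\n")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected matrix TSV at {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "vertex_index":
        raise InputError(f"{path} is not a vertex-indexed matrix TSV")
    df = df.sort_values("vertex_index")
    cols = list(df.columns[1:])
    return df[cols].to_numpy(dtype=float), cols


def write_placements(placements: list[CoilPlacement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("row\tcol\ttheta_deg\tx\ty\tz\n")
        for p in placements:
            fh.write(
                f"{p.row}\t{p.col}\t{p.theta_deg}\t"
                + "\t".join(FLOAT_FMT % v for v in p.center)
                + "\n"
            )


def read_placements(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expected placement manifest at {path}")
    return pd.read_csv(path, sep="\t")


def _write_summary(summary, out: Path) -> None:
    overall = summary.overall_percent.rename_axis("network").rename("percent")
    overall.to_frame().to_csv(out / "summary_overall.tsv", sep="\t",
                              float_format=FLOAT_FMT)
    zc = summary.zone_counts.copy()
    zc["modal_networks"] = [
        ",".join(map(str, summary.zone_modal[z])) for z in zc.index
    ]
    zc.to_csv(out / "summary_zone.tsv", sep="\t")
    zw = summary.zone_window_counts.copy()
    zw["modal_networks"] = [
        ",".join(map(str, summary.zone_window_modal[tuple(k)])) for k in zw.index
    ]
    zw.to_csv(out / "summary_zone_window.tsv", sep="\t")


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the artifact set to ``out_dir``.

    Identical (config, seed) runs produce byte-identical outputs.  Returns a
    dict of the in-memory stage products for programmatic use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mesh, parc = stage_surface(config)
    write_ply(mesh, out / "mesh.ply")
    write_parcellation(parc, out / "parcellation.tsv")

    placements, fields = stage_fields(config, mesh)
    keys = [placement_key(*p.key) for p in placements]
    write_placements(placements, out / "placements.tsv")
    if config.write_field_maps:
        write_matrix_tsv(
            np.stack([f.values for f in fields], axis=1), keys, out / "fields.tsv"
        )

    ts = stage_fmri(config, parc)
    if config.write_timeseries:
        write_timeseries(ts, out / "timeseries.tsv")

    maps, seed_series, covariate = stage_connectivity(config, fields, ts)
    if config.write_connectivity_maps:
        write_matrix_tsv(
            np.stack([m.values for m in maps], axis=1), keys, out / "connectivity.tsv"
        )

    results = stage_assign(config, maps, placements, parc)
    results_frame(results).to_csv(
        out / "results.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    summary = summarize(results)
    _write_summary(summary, out)

    efsi_map = efsi(fields, config.efsi_fraction)
    write_vertex_metric(efsi_map.values, out / "efsi.tsv", column="efsi_pct")
    per_map = per_map_suprathreshold_fraction(fields, config.efsi_fraction)
    with open(out / "efsi_per_map.tsv", "w") as fh:
        fh.write("placement\tsuprathreshold_pct\n")
        for key, val in zip(keys, per_map):
            fh.write(f"{key}\t{FLOAT_FMT % val}\n")

    provenance = {
        "package": "tmsnet",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "mesh": mesh,
        "parcellation": parc,
        "placements": placements,
        "fields": fields,
        "timeseries": ts,
        "connectivity": maps,
        "seed_series": seed_series,
        "covariate": covariate,
        "results": results,
        "summary": summary,
        "efsi": efsi_map,
        "efsi_per_map": per_map,
    }
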