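"""Plain-text I/O for photon streams, cohort manifests and results.

Photon streams are one decimal timestamp (seconds) per line with a
``#``-prefixed header carrying molecule_id and substrate.  Timestamps are
written with the shortest decimal representation that round-trips the
underlying float exactly, so write -> read is lossless.  Manifests and
result tables are CSV; run metadata is JSON.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .enhancement import GROUPS, EnhancementResult, GroupStats, IntensityResult, StateSummary
from .errors import ConsistencyError, CorruptInputError, InvalidConfigError
from .reconstruct import StatePath
from .simulate import GroundTruthPath, PhotonTrajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_ground_truth",
    "read_ground_truth",
    "CohortManifest",
    "write_manifest",
    "read_manifest",
    "write_results",
    "read_enhancement_table",
]

SUBSTRATES = ("glass", "ZMW", "synthetic")


def _fmt(x: float) -> str:
    return np.format_float_positional(x, unique=True, trim="0")


def write_trajectory(traj: PhotonTrajectory, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# molecule_id: {traj.molecule_id}\n")
        fh.write(f"# substrate: {traj.substrate}\n")
        for t in traj.arrival_times:
            fh.write(_fmt(t) + "\n")


def read_trajectory(path) -> PhotonTrajectory:
    """Parse a plain-text photon stream, validating monotonicity on read."""
    path = Path(path)
    meta = {"molecule_id": path.stem, "substrate": "synthetic"}
    times = []
    prev = -np.inf
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            try:
                t = float(line)
            except ValueError:
                raise CorruptInputError(f"{path}: non-numeric timestamp at line {lineno}: {line!r}")
            if not np.isfinite(t) or t < 0:
                raise CorruptInputError(f"{path}: invalid timestamp at line {lineno}: {line!r}")
            if t <= prev:
                raise CorruptInputError(f"{path}: non-increasing timestamp at line {lineno}")
            times.append(t)
            prev = t
    return PhotonTrajectory(
        arrival_times=np.array(times, dtype=float),
        substrate=meta["substrate"],
        molecule_id=meta["molecule_id"],
    )


def write_ground_truth(truth: GroundTruthPath, path) -> None:
    df = pd.DataFrame(truth.segments, columns=["segment_start", "segment_end", "state_index"])
    df.to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruthPath:
    df = pd.read_csv(path)
    segs = tuple(
        (float(r.segment_start), float(r.segment_end), int(r.state_index))
        for r in df.itertuples()
    )
    return GroundTruthPath(segments=segs)


@dataclass(frozen=True)
class CohortManifest:
    """Rows of (file, molecule_id, substrate) plus a provenance block."""

    rows: tuple[tuple[str, str, str], ...]
    provenance: dict

    def __post_init__(self):
        ids = [r[1] for r in self.rows]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError("molecule_ids in a manifest must be unique")
        for _, mid, sub in self.rows:
            if sub not in SUBSTRATES[:2]:
                raise InvalidConfigError(f"{mid}: substrate must be glass or ZMW, got {sub!r}")


def write_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# provenance: " + json.dumps(manifest.provenance, sort_keys=True) + "\n")
        fh.write("file,molecule_id,substrate\n")
        for file, mid, sub in manifest.rows:
            fh.write(f"{file},{mid},{sub}\n")


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    provenance = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = json.loads(first.partition("# provenance:")[2])
    df = pd.read_csv(path, comment="#")
    rows = tuple((str(r.file), str(r.molecule_id), str(r.substrate)) for r in df.itertuples())
    return CohortManifest(rows=rows, provenance=provenance)


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    summaries: dict[str, list[StateSummary]],
    intensities: list[IntensityResult],
    enhancement: EnhancementResult | None,
    out_dir,
    config: AnalysisConfig | None = None,
) -> dict[str, Path]:
    """Write per-molecule summaries, intensities and the four-row
    enhancement table as CSV, plus JSON run metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intensity_ids = {r.molecule_id for r in intensities}
    if not intensity_ids <= set(summaries):
        raise ConsistencyError(
            f"intensity results for unknown molecules: {sorted(intensity_ids - set(summaries))}"
        )
    paths: dict[str, Path] = {}

    rows = []
    for mid in sorted(summaries):
        for s in summaries[mid]:
            rows.append(
                {
                    "molecule_id": mid,
                    "state": s.state,
                    "n_intervals": s.n_intervals,
                    "total_time_s": s.total_time,
                    "mean_interphoton_time_s": s.mean_interphoton_time,
                    "count_rate_per_s": s.count_rate,
                }
            )
    paths["state_summaries"] = out_dir / "state_summaries.csv"
    pd.DataFrame(rows).to_csv(paths["state_summaries"], index=False)

    rows = []
    for r in sorted(intensities, key=lambda r: r.molecule_id):
        for n, val in sorted(r.intensities.items()):
            rows.append(
                {
                    "molecule_id": r.molecule_id,
                    "substrate": r.substrate,
                    "n_states": r.n_states,
                    "state": n,
                    "intensity_per_s": val,
                    "flagged_negative": r.flagged_negative,
                }
            )
    paths["intensities"] = out_dir / "intensities.csv"
    pd.DataFrame(rows).to_csv(paths["intensities"], index=False)

    if enhancement is not None:
        rows = []
        for g in (g for g in GROUPS if g in enhancement.ef):
            rows.append(
                {
                    "distribution": g,
                    "glass_mean": enhancement.glass[g].mean,
                    "glass_se": enhancement.glass[g].std_error,
                    "glass_n": enhancement.glass[g].n,
                    "zmw_mean": enhancement.zmw[g].mean,
                    "zmw_se": enhancement.zmw[g].std_error,
                    "zmw_n": enhancement.zmw[g].n,
                    "ef": enhancement.ef[g],
                    "ef_rounded": enhancement.ef_rounded[g],
                }
            )
        paths["enhancement"] = out_dir / "enhancement.csv"
        pd.DataFrame(rows).to_csv(paths["enhancement"], index=False)

    cfg = config or AnalysisConfig()
    meta = {
        "tool": "photonpath",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "n_molecules": len(summaries),
        "outlier_excluded_ids": list(enhancement.excluded_ids) if enhancement else [],
    }
    paths["metadata"] = out_dir / "run_metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return paths


def read_enhancement_table(path) -> EnhancementResult:
    """Rebuild an EnhancementResult (summary statistics only) from the
    written enhancement CSV."""
    df = pd.read_csv(path)
    glass, zmw, ef, ef_rounded = {}, {}, {}, {}
    for r in df.itertuples():
        g = r.distribution
        glass[g] = GroupStats(mean=r.glass_mean, std_error=r.glass_se, n=int(r.glass_n))
        zmw[g] = GroupStats(mean=r.zmw_mean, std_error=r.zmw_se, n=int(r.zmw_n))
        ef[g] = float(r.ef)
        ef_rounded[g] = float(r.ef_rounded)
    return EnhancementResult(
        glass=glass, zmw=zmw, ef=ef, ef_rounded=ef_rounded,
        outlier_threshold=None, excluded_ids=(),
    )
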