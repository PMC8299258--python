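"""Text-format readers and writers.

Everything is diffable plain text: curves as TSV with a '#'-prefixed
metadata header, ground truth and manifests as JSON, event tables as TSV.
Outputs are deterministic (fixed float formats, sorted JSON keys, no
timestamps) so reruns with the same seeds are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .curve_analysis import CurveResult, ForceExtensionCurve
from .synthetic import GroundTruthRecord, TruthEvent

__all__ = [
    "CurveFormatError",
    "write_curve_tsv",
    "read_curve_tsv",
    "write_truth_json",
    "read_truth_json",
    "write_dataset",
    "read_dataset",
    "events_dataframe",
    "write_events_tsv",
    "read_events_tsv",
    "read_force_rate_tsv",
]


class CurveFormatError(ValueError):
    """Malformed curve or table file; the message carries the line number."""


def write_curve_tsv(curve: ForceExtensionCurve, path) -> None:
    path = Path(path)
    lines = []
    for key in sorted(curve.metadata):
        lines.append(f"# {key}\t{curve.metadata[key]}")
    lines.append("extension_nm\tforce_pN")
    for x, f in zip(curve.extension, curve.force):
        lines.append(f"{x:.4f}\t{f:.3f}")
    path.write_text("\n".join(lines) + "\n")


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def read_curve_tsv(path) -> ForceExtensionCurve:
    path = Path(path)
    metadata: dict = {}
    ext, force = [], []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t", 1)
            if len(parts) == 2:
                metadata[parts[0]] = _coerce(parts[1])
            continue
        if not header_seen:
            if line.split("\t")[:2] != ["extension_nm", "force_pN"]:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: expected 'extension_nm\\tforce_pN' header"
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CurveFormatError(
                f"{path.name}:{lineno}: expected 2 tab-separated columns"
            )
        try:
            ext.append(float(parts[0]))
            force.append(float(parts[1]))
        except ValueError:
            raise CurveFormatError(
                f"{path.name}:{lineno}: non-numeric value"
            ) from None
    if not header_seen:
        raise CurveFormatError(f"{path.name}: no data header found")
    return ForceExtensionCurve(extension=ext, force=force, metadata=metadata)


def write_truth_json(truth: GroundTruthRecord, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True) + "\n"
    )


def read_truth_json(path) -> GroundTruthRecord:
    data = json.loads(Path(path).read_text())
    events = [TruthEvent(**e) for e in data.pop("events")]
    return GroundTruthRecord(events=events, **data)


def write_dataset(results, config, master_seed: int, out_dir) -> dict:
    """Write curves + truth sidecars + manifest for one simulated dataset."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (curve, truth) in enumerate(results):
        stem = f"curve_{i:04d}"
        write_curve_tsv(curve, out / f"{stem}.tsv")
        write_truth_json(truth, out / f"{stem}.truth.json")
        entries.append(
            {
                "file": f"{stem}.tsv",
                "truth_file": f"{stem}.truth.json",
                "curve_id": truth.curve_id,
                "seed": truth.seed,
            }
        )
    manifest = {
        "version": __version__,
        "master_seed": int(master_seed),
        "n_curves": len(results),
        "construct": results[0][1].construct,
        "pulling_speed_nm_s": config.pulling_speed,
        "cantilever_stiffness_pN_nm": config.cantilever_stiffness,
        "force_noise_sd_pN": config.force_noise_sd,
        "sampling_interval_nm": config.sampling_interval,
        "curves": entries,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def read_dataset(data_dir):
    """Yield curves listed in a dataset manifest (or every *.tsv if none)."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        files = [data_dir / e["file"] for e in manifest["curves"]]
    else:
        files = sorted(p for p in data_dir.glob("*.tsv") if ".truth" not in p.name)
    if not files:
        raise FileNotFoundError(f"no curve files found in {data_dir}")
    for f in files:
        yield read_curve_tsv(f)


def events_dataframe(results: list[CurveResult]) -> pd.DataFrame:
    """Flatten per-curve analyses into the events table."""
    rows = []
    for res in results:
        cid = res.curve.metadata.get("curve_id", "")
        for pk in res.peaks:
            rows.append(
                {
                    "curve_id": cid,
                    "peak_index": pk.peak_index,
                    "rupture_force_pN": round(pk.rupture_force, 3),
                    "Lc_nm": (
                        round(pk.fitted_contour_length, 4)
                        if pk.fitted_contour_length is not None
                        else float("nan")
                    ),
                    "dlc_nm": round(pk.dlc, 4) if pk.dlc is not None else float("nan"),
                    "loading_rate_pN_s": (
                        round(pk.loading_rate, 2)
                        if pk.loading_rate is not None
                        else float("nan")
                    ),
                    "attribution": pk.attribution,
                    "accepted": res.accepted,
                }
            )
    return pd.DataFrame(rows)


def write_events_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def read_force_rate_tsv(path) -> pd.DataFrame:
    """Bare two-column (force_pN, loading_rate_pN_s) TSV for DFS input."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:2])
    df = df.rename(columns={cols[0]: "rupture_force_pN", cols[1]: "loading_rate_pN_s"})
    return df
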