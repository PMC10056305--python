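"""Format readers and writers.

Covers a minimal dialect of the WFDB record format (text ``.hea`` header
plus interleaved little-endian int16 ``.dat``, format 16, physical units
restored from gain/baseline), 1-bit PNG + JSON sidecar persistence for
phase portraits, and the sweep-result CSV files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phase_space import PhasePortrait
from .experiment import SweepResult, stage_averages
from .synthetic import EcgRecord

WFDB_GAIN = 1000.0  # ADC units per mV; 16-bit range then spans +-32 mV
_STAGE_LABELS = ("16-30", "31-45", "46-60", "61-75")


def write_wfdb_record(record: EcgRecord, out_dir: str | Path,
                      lead: str = "I") -> Path:
    """Write a single-signal WFDB-compatible record (format 16).

    Returns the header path.  Ground-truth R locations, when present, go
    to ``<name>.rloc`` (one sample index per line).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = record.subject_id
    digital = np.clip(np.round(record.samples * WFDB_GAIN),
                      -32768, 32767).astype("<i2")
    (out_dir / f"{name}.dat").write_bytes(digital.tobytes())
    header = (
        f"{name} 1 {record.fs:g} {record.samples.size}\n"
        f"{name}.dat 16 {WFDB_GAIN:g}(0)/mV 16 0 {int(digital[0])} 0 0 {lead}\n"
    )
    hea = out_dir / f"{name}.hea"
    hea.write_text(header)
    if record.true_r_locations is not None:
        (out_dir / f"{name}.rloc").write_text(
            "\n".join(str(int(i)) for i in record.true_r_locations) + "\n")
    return hea


def _parse_gain(spec: str) -> tuple[float, float, str]:
    """Parse a WFDB gain token like '1000(0)/mV' -> (gain, baseline, units)."""
    units = "mV"
    if "/" in spec:
        spec, units = spec.split("/", 1)
    baseline = 0.0
    if "(" in spec:
        spec, rest = spec.split("(", 1)
        baseline = float(rest.rstrip(")"))
    gain = float(spec) if spec else 200.0
    return (gain if gain != 0 else 200.0), baseline, units


def read_wfdb_record(header_path: str | Path, lead: str = "I") -> EcgRecord:
    """Read one lead of a WFDB format-16 record in physical units (mV).

    Lead names are matched case-insensitively against the signal
    description (last header token); a missing lead raises an error that
    lists the available leads.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    lines = [l.strip() for l in header_path.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    rec_tokens = lines[0].split()
    name, nsig = rec_tokens[0], int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0

    leads, sig_rows = [], []
    for row in lines[1:1 + nsig]:
        tokens = row.split()
        desc = tokens[-1] if len(tokens) >= 9 else f"sig{len(sig_rows)}"
        leads.append(desc)
        sig_rows.append(tokens)
    matches = [i for i, l in enumerate(leads) if l.lower() == lead.lower()]
    if not matches:
        raise ValueError(f"lead {lead!r} not found; available leads: "
                         f"{', '.join(leads)}")
    idx = matches[0]
    tokens = sig_rows[idx]
    fmt = tokens[1].split("x")[0].split(":")[0]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB format {fmt!r} (only 16)")
    gain, baseline, _ = _parse_gain(tokens[2]) if len(tokens) > 2 else (200.0, 0.0, "mV")

    dat_path = header_path.parent / tokens[0]
    raw = np.frombuffer(dat_path.read_bytes(), dtype="<i2")
    sig = raw.reshape(-1, nsig)[:, idx].astype(float)
    samples = (sig - baseline) / gain

    rloc_path = header_path.parent / f"{name}.rloc"
    rlocs = None
    if rloc_path.exists():
        rlocs = np.array([int(l) for l in rloc_path.read_text().split()],
                         dtype=int)
    return EcgRecord(samples=samples, fs=fs, subject_id=name,
                     true_r_locations=rlocs)


def save_portrait(portrait: PhasePortrait, path: str | Path) -> Path:
    """Persist a portrait as a 1-bit PNG with a JSON metadata sidecar."""
    path = Path(path).with_suffix(".png")
    img = Image.fromarray(portrait.image.astype(bool))
    img.save(path, optimize=True)
    meta = {
        "tau_ms": portrait.tau_ms,
        "partitions": portrait.partitions,
        "out_pixels": int(portrait.image.shape[0]),
        "subject_id": portrait.subject_id,
        "grid": portrait.grid.astype(int).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def load_portrait(path: str | Path) -> PhasePortrait:
    path = Path(path).with_suffix(".png")
    meta = json.loads(path.with_suffix(".json").read_text())
    image = np.asarray(Image.open(path), dtype=np.uint8)
    if image.shape != (meta["out_pixels"], meta["out_pixels"]):
        raise ValueError(
            f"sidecar out_pixels={meta['out_pixels']} does not match image "
            f"dimensions {image.shape}")
    return PhasePortrait(grid=np.asarray(meta["grid"], dtype=np.uint8),
                         tau_ms=meta["tau_ms"], partitions=meta["partitions"],
                         image=image, subject_id=meta["subject_id"])


def write_results(result: SweepResult, out_dir: str | Path) -> Path:
    """Write per-epoch and stage-average CSVs (accuracy at 2 decimals).

    Failed sweep cells are flagged in ``failures.csv``, never dropped
    silently.  Row order is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (tau, grid) in sorted(result.traces):
        for epoch, acc in enumerate(result.traces[(tau, grid)], start=1):
            rows.append((tau, grid, epoch, f"{acc:.2f}"))
    df = pd.DataFrame(rows, columns=["tau_ms", "grid", "epoch", "val_accuracy"])
    df.to_csv(out_dir / "results.csv", index=False)

    stage_rows = []
    for (tau, grid) in sorted(result.traces):
        avgs = result.stage_avgs.get((tau, grid)) or stage_averages(
            result.traces[(tau, grid)])
        for label, avg in zip(_STAGE_LABELS, avgs):
            stage_rows.append((tau, grid, label, f"{avg:.2f}"))
    pd.DataFrame(stage_rows, columns=["tau_ms", "grid", "stage",
                                      "avg_accuracy"]).to_csv(
        out_dir / "stage_averages.csv", index=False)

    if result.failures:
        fail_rows = [(tau, grid, reason)
                     for (tau, grid), reason in sorted(result.failures.items())]
        pd.DataFrame(fail_rows, columns=["tau_ms", "grid", "reason"]).to_csv(
            out_dir / "failures.csv", index=False)
    return out_dir / "results.csv"


def read_results(out_dir: str | Path) -> SweepResult:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "results.csv")
    result = SweepResult()
    for (tau, grid), sub in df.groupby(["tau_ms", "grid"]):
        trace = list(sub.sort_values("epoch")["val_accuracy"].astype(float))
        result.traces[(tau, grid)] = trace
        result.stage_avgs[(tau, grid)] = stage_averages(trace)
    fail_path = out_dir / "failures.csv"
    if fail_path.exists():
        for _, row in pd.read_csv(fail_path).iterrows():
            result.failures[(row["tau_ms"], row["grid"])] = row["reason"]
    return result


def plot_stage_heatmap(result: SweepResult, stage_index: int,
                       path: str | Path) -> Path:
    """Heatmap of stage-average accuracy over the (tau, grid) factorial."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    taus = sorted({t for t, _ in result.stage_avgs})
    grids = sorted({g for _, g in result.stage_avgs})
    mat = np.full((len(taus), len(grids)), np.nan)
    for i, t in enumerate(taus):
        for j, g in enumerate(grids):
            avgs = result.stage_avgs.get((t, g))
            if avgs and len(avgs) > stage_index:
                mat[i, j] = avgs[stage_index]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(grids)), [f"{g}x{g}" for g in grids])
    ax.set_yticks(range(len(taus)), [f"{t} ms" for t in taus])
    ax.set_xlabel("grid partition")
    ax.set_ylabel("time delay")
    ax.set_title(f"validation accuracy, epochs {_STAGE_LABELS[stage_index]}")
    fig.colorbar(im, ax=ax, label="accuracy (%)")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
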