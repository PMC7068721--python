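"""File interfaces.

Continuous recordings travel as a documented tab-separated dialect
(header comments, then columns ``time_s  ch1..ch8`` in microvolts) with a
companion events file (``onset_sample  condition  stimulus_id``); epoch
sets as a directory of per-epoch TSV files plus a JSON sidecar of labels
and validity.  EDF recordings can be *read* via MNE when it is
installed; writing uses the text dialect.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CHANNELS, EpochSet, Recording


def write_recording_tsv(rec: Recording, signal_path, events_path) -> None:
    signal_path, events_path = Path(signal_path), Path(events_path)
    t = np.arange(rec.n_times) / rec.sample_rate_hz
    with open(signal_path, "w") as fh:
        fh.write(f"# sample_rate_hz\t{rec.sample_rate_hz}\n")
        fh.write(f"# reference\t{rec.reference}\n")
        fh.write("# units\tmicrovolts\n")
        fh.write("time_s\t" + "\t".join(rec.channel_names) + "\n")
        np.savetxt(fh, np.column_stack([t, rec.samples.T]),
                   delimiter="\t", fmt="%.6f")
    rec.events[["onset_sample", "condition", "stimulus_id"]].to_csv(
        events_path, sep="\t", index=False)


def read_recording_tsv(signal_path, events_path) -> Recording:
    signal_path, events_path = Path(signal_path), Path(events_path)
    meta: dict[str, str] = {}
    with open(signal_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    channels = tuple(c for c in table.columns if c != "time_s")
    events = pd.read_csv(events_path, sep="\t")
    if "ordinal" not in events.columns:
        events["ordinal"] = events.groupby("condition").cumcount()
    return Recording(
        samples=table[list(channels)].to_numpy().T,
        sample_rate_hz=float(meta.get("sample_rate_hz", 500.0)),
        events=events,
        channel_names=channels,
        reference=meta.get("reference", "left mastoid"),
    )


def read_recording_edf(edf_path, events_path) -> Recording:
    """Read a continuous recording from EDF (requires mne) and events
    from the TSV events file."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne; install the 'edf' extra or use "
            "the TSV dialect (read_recording_tsv)") from exc
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    picks = [ch for ch in raw.ch_names if ch in CHANNELS] or raw.ch_names
    data = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    events = pd.read_csv(events_path, sep="\t")
    if "ordinal" not in events.columns:
        events["ordinal"] = events.groupby("condition").cumcount()
    return Recording(
        samples=data, sample_rate_hz=float(raw.info["sfreq"]),
        events=events, channel_names=tuple(picks),
    )


def write_epochs_dir(es: EpochSet, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "sample_rate_hz": es.sample_rate_hz,
        "channel_names": list(es.channel_names),
        "times_ms": es.times_ms.tolist(),
        "epochs": [
            {
                "file": f"epoch_{i:04d}.tsv",
                "condition": str(es.conditions[i]),
                "ordinal": int(es.ordinals[i]),
                "valid": bool(es.valid[i]),
                "kept": bool(es.kept[i]),
                "reason": str(es.reason[i]),
            }
            for i in range(len(es))
        ],
        "meta": {k: v for k, v in es.meta.items()
                 if isinstance(v, (str, int, float, bool, list, dict))},
    }
    (out_dir / "epochs.json").write_text(json.dumps(sidecar, indent=1))
    header = "\t".join(es.channel_names)
    for i in range(len(es)):
        np.savetxt(out_dir / f"epoch_{i:04d}.tsv", es.data[i].T,
                   delimiter="\t", fmt="%.6f", header=header,
                   comments="")


def read_epochs_dir(in_dir) -> EpochSet:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "epochs.json").read_text())
    infos = sidecar["epochs"]
    data = np.stack([
        pd.read_csv(in_dir / info["file"], sep="\t").to_numpy().T
        for info in infos
    ]) if infos else np.empty((0, len(sidecar["channel_names"]),
                               len(sidecar["times_ms"])))
    return EpochSet(
        data=data,
        times_ms=np.asarray(sidecar["times_ms"], float),
        conditions=np.array([i["condition"] for i in infos], dtype=object),
        ordinals=np.array([i["ordinal"] for i in infos], dtype=int),
        sample_rate_hz=float(sidecar["sample_rate_hz"]),
        channel_names=tuple(sidecar["channel_names"]),
        valid=np.array([i["valid"] for i in infos], dtype=bool),
        reason=np.array([i["reason"] for i in infos], dtype=object),
        kept=np.array([i["kept"] for i in infos], dtype=bool),
        meta=sidecar.get("meta", {}),
    )
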