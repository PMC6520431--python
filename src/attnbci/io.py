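"""Recording and cohort I/O: EDF signals, JSON annotations, CSV manifests.

Recordings are written as EDF (European Data Format, 16-bit), one file per
subject, with a JSON sidecar carrying the round annotations and any
synthesis ground truth (EDF has no native annotation channel in its base
form).  Reading goes through MNE's EDF reader, which also serves as an
independent check on the writer in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage
from .synth import Recording, Round


def write_edf(rec: Recording, path) -> None:
    """Write a recording as a 16-bit EDF file (one 1 s data record per second).

    Requires an integer sampling rate and an integer number of seconds;
    physical units are microvolts with per-channel symmetric scaling.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_t = rec.samples.shape
    if n_t % fs != 0:
        raise ValueError("EDF export needs a whole number of seconds")
    n_records = n_t // fs

    # per-channel symmetric physical range, padded so the digital grid is exact
    phys_max = np.maximum(np.abs(rec.samples).max(axis=1) * 1.01, 1.0)
    if (phys_max > 9999).any():
        raise ValueError("signal amplitude exceeds the 9999 uV EDF header budget")
    dig_max, dig_min = 32767, -32768

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),  # version
            pad(f"subject {rec.subject_id}", 80),
            pad("attnbci synthetic recording", 80),
            pad("01.01.00", 8),  # start date (synthetic)
            pad("00.00.00", 8),  # start time
            pad(str(256 * (n_ch + 1)), 8),
            pad("", 44),  # reserved
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, s
            pad(str(n_ch), 4),
        ]
    )
    labels = b"".join(pad(f"EEG {c}", 16) for c in rec.montage.channel_names)
    transducer = b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch))
    phys_dim = b"".join(pad("uV", 8) for _ in range(n_ch))
    phys_min_b = b"".join(pad(f"{-m:.2f}", 8) for m in phys_max)
    phys_max_b = b"".join(pad(f"{m:.2f}", 8) for m in phys_max)
    dig_min_b = b"".join(pad(str(dig_min), 8) for _ in range(n_ch))
    dig_max_b = b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    prefilter = b"".join(pad("", 80) for _ in range(n_ch))
    n_samp = b"".join(pad(str(fs), 8) for _ in range(n_ch))
    reserved = b"".join(pad("", 32) for _ in range(n_ch))

    # the physical range actually written is the one re-parsed from the
    # 8-char ASCII fields, so quantization must use the parsed values
    parsed_max = np.array([float(f"{m:.2f}") for m in phys_max])
    scale = ((dig_max - dig_min) / (2 * parsed_max))[:, None]
    digital = np.round((rec.samples + parsed_max[:, None]) * scale + dig_min).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + phys_min_b + phys_max_b)
        fh.write(dig_min_b + dig_max_b + prefilter + n_samp + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def write_sidecar(rec: Recording, path, extra: dict | None = None) -> None:
    """JSON sidecar with fs, subject, round annotations and optional ground truth."""
    payload = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "channel_names": list(rec.montage.channel_names),
        "rounds": [
            {"start_s": r.start_s, "end_s": r.end_s, "label": r.label} for r in rec.rounds
        ],
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_recording(edf_path, sidecar_path) -> Recording:
    """Load a recording from EDF + JSON sidecar via MNE's EDF reader."""
    import mne

    meta = json.loads(Path(sidecar_path).read_text())
    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE scales uV channels to volts
    montage = Montage(channel_names=tuple(meta["channel_names"]))
    rounds = [Round(r["start_s"], r["end_s"], r["label"]) for r in meta["rounds"]]
    return Recording(data, float(meta["fs"]), montage, rounds, meta["subject_id"])


def save_cohort(recs: list[Recording], out_dir, truths: dict | None = None) -> pd.DataFrame:
    """Write one EDF + sidecar per subject and a cohort manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recs:
        edf = out_dir / f"{rec.subject_id}.edf"
        sidecar = out_dir / f"{rec.subject_id}.json"
        extra = None
        if truths and rec.subject_id in truths:
            t = truths[rec.subject_id]
            extra = {
                "blink_onsets_s": list(map(float, t.onsets_s)),
                "blink_mixing": list(map(float, t.mixing)),
            }
        write_edf(rec, edf)
        write_sidecar(rec, sidecar, extra)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "edf": edf.name,
                "sidecar": sidecar.name,
                "fs": rec.fs,
                "n_rounds": len(rec.rounds),
                "duration_s": rec.duration_s,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_cohort(out_dir) -> list[Recording]:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    return [
        read_recording(out_dir / row.edf, out_dir / row.sidecar)
        for row in manifest.itertuples()
    ]
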