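"""Session I/O (EDF+ and an internal HDF5 container) and epoch extraction.

EDF is the interchange format: 16-bit quantized, annotations carry the
S1/S2 event stream. The internal container keeps signals at native
float precision for exact round trips. Reading EDF goes through MNE's
reader; the EDF+ writer lives here because the quantization and TAL
annotation layout are simple enough to emit directly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, EpochSet, RawSession, pool_classes
from .montage import Montage, infer_kind, scalp_xy

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when a file lacks the structure a session needs."""


# --------------------------------------------------------------------
# internal HDF5 container
# --------------------------------------------------------------------

def _write_h5(session: RawSession, path: Path) -> None:
    meta = {
        "subject": session.subject,
        "condition": session.condition,
        "sample_rate": session.sample_rate,
        "channel_names": list(session.montage.names),
        "channel_kinds": list(session.montage.kinds),
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=session.signal)
        f.create_dataset("positions", data=session.montage.positions)
        f.attrs["meta"] = json.dumps(meta)
        f.attrs["events"] = session.events.to_json(orient="split")
        if session.onsets is not None:
            f.attrs["onsets"] = session.onsets.to_json(orient="split")


def _read_h5(path: Path) -> RawSession:
    from io import StringIO

    with h5py.File(path, "r") as f:
        if "signal" not in f or "meta" not in f.attrs:
            raise FormatError(f"{path} is not an mrcperd session container")
        sig = f["signal"][()]
        pos = f["positions"][()]
        meta = json.loads(f.attrs["meta"])
        events = pd.read_json(StringIO(f.attrs["events"]), orient="split")
        onsets = (
            pd.read_json(StringIO(f.attrs["onsets"]), orient="split")
            if "onsets" in f.attrs else None
        )
    events = events.astype(
        {"trial": int, "block": int, "s1_time": float, "s2_time": float}
    )
    if onsets is not None:
        onsets = onsets.astype({"trial": int, "onset_time": float})
    montage = Montage(tuple(meta["channel_names"]), tuple(meta["channel_kinds"]), pos)
    return RawSession(
        subject=meta["subject"], condition=meta["condition"], signal=sig,
        sample_rate=meta["sample_rate"], montage=montage, events=events, onsets=onsets,
    )


# --------------------------------------------------------------------
# EDF+ writer
# --------------------------------------------------------------------

_ANNOT_BYTES = 256  # per-record TAL budget for the annotation signal


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(session: RawSession, path: Path) -> None:
    fs = session.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    n_ch = session.signal.shape[0]
    n_samples = session.signal.shape[1]
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = session.signal

    # physical scaling per channel: symmetric range covering the data
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6) * 1.0000001
    dig_max = 32767
    labels = [f"{k} {n}" if k in ("EOG",) else n for n, k in
              zip(session.montage.names, session.montage.kinds)]

    # annotation TAL streams, one per record
    events_by_rec: list[list[str]] = [[] for _ in range(n_records)]
    for _, row in session.events.iterrows():
        for tag, tcol in (("S1", "s1_time"), ("S2", "s2_time")):
            t0 = float(row[tcol])
            text = f"{tag}/{row['movement']}/b{int(row['block'])}/t{int(row['trial'])}"
            rec = min(int(t0), n_records - 1)
            events_by_rec[rec].append(f"+{t0:.4f}\x14{text}\x14\x00")

    ann_streams = []
    for rec in range(n_records):
        s = f"+{rec}\x14\x14\x00" + "".join(events_by_rec[rec])
        b = s.encode("utf-8")
        if len(b) > _ANNOT_BYTES:
            raise ValueError("annotation record overflow; increase _ANNOT_BYTES")
        ann_streams.append(b.ljust(_ANNOT_BYTES, b"\x00"))

    ns = n_ch + 1  # + annotation signal
    header = b"".join([
        _edf_field(0, 8),
        _edf_field(f"{session.subject} X X X", 80),
        _edf_field(f"Startdate X X X X cond_{session.condition}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),  # record duration, seconds
        _edf_field(ns, 4),
    ])
    sig_labels = labels + ["EDF Annotations"]
    transducer = [""] * ns
    phys_dim = ["uV" if k in ("EEG", "EOG") else "" for k in session.montage.kinds] + [""]
    pmin = [f"{-m:.6g}"[:8] for m in phys_max] + ["-1"]
    pmax = [f"{m:.6g}"[:8] for m in phys_max] + ["1"]
    dmin = [str(-dig_max)] * n_ch + ["-32768"]
    dmax = [str(dig_max)] * n_ch + ["32767"]
    prefilter = [""] * ns
    nsamp = [str(fs)] * n_ch + [str(_ANNOT_BYTES // 2)]
    for fields, width in (
        (sig_labels, 16), (transducer, 80), (phys_dim, 8), (pmin, 8), (pmax, 8),
        (dmin, 8), (dmax, 8), (prefilter, 80), (nsamp, 8),
    ):
        header += b"".join(_edf_field(v, width) for v in fields)
    header += b" " * (32 * ns)  # reserved

    scale = dig_max / phys_max
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = padded[:, rec * fs : (rec + 1) * fs]
            dig = np.round(chunk * scale[:, None]).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(ann_streams[rec])


def _read_edf(path: Path) -> RawSession:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ann = raw.annotations
    if len(ann) == 0 or not any(d.startswith("S2") for d in ann.description):
        raise FormatError(f"{path}: no S2 annotations; cannot reconstruct the event table")

    names, kinds = [], []
    for ch in raw.ch_names:
        name = ch.split()[-1]  # strip "EOG " style prefixes
        names.append(name)
        kinds.append(infer_kind(name))
    pos = np.full((len(names), 2), np.nan)
    eeg_rows = [i for i, k in enumerate(kinds) if k == "EEG"]
    pos[eeg_rows] = scalp_xy([names[i] for i in eeg_rows])
    montage = Montage(tuple(names), tuple(kinds), pos)

    data = raw.get_data()  # SI units for recognised dims
    sig = data.copy()
    for i, k in enumerate(kinds):
        if k in ("EEG", "EOG"):
            sig[i] = data[i] * 1e6  # V -> µV

    trials: dict[int, dict] = {}
    for onset, desc in zip(ann.onset, ann.description):
        parts = desc.split("/")
        if len(parts) != 4 or parts[0] not in ("S1", "S2"):
            continue
        tag, movement, block, trial = parts
        ti = int(trial[1:])
        d = trials.setdefault(ti, {"trial": ti, "block": int(block[1:]), "movement": movement})
        d["s1_time" if tag == "S1" else "s2_time"] = float(onset)
    rows = [trials[k] for k in sorted(trials)]
    events = pd.DataFrame(rows)
    if "s2_time" not in events.columns or events["s2_time"].isna().any():
        raise FormatError(f"{path}: incomplete S2 annotations")
    events = events[EVENT_COLUMNS]

    # subject and condition are stamped in the EDF id fields
    with open(path, "rb") as fh:
        fh.seek(8)
        pat_id = fh.read(80).decode("ascii", "ignore")
        rec_id = fh.read(80).decode("ascii", "ignore")
    cond = "MI" if "cond_MI" in rec_id else "ME"
    subject = pat_id.split()[0] if pat_id.split() else "S?"
    return RawSession(
        subject=subject, condition=cond, signal=sig, sample_rate=float(raw.info["sfreq"]),
        montage=montage, events=events,
    )


# --------------------------------------------------------------------
# public API
# --------------------------------------------------------------------

def write_session(session: RawSession, path: str | Path, dialect: str = "internal") -> Path:
    """Write a session; ``dialect`` is ``'EDF'`` or ``'internal'``."""
    path = Path(path)
    if session.signal.size == 0:
        raise ValueError("refusing to write a zero-length signal")
    if dialect.upper() == "EDF":
        _write_edf(session, path)
    elif dialect == "internal":
        _write_h5(session, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_session(path: str | Path, dialect: str | None = None) -> RawSession:
    """Read a session, sniffing the dialect from the file when not given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        with open(path, "rb") as fh:
            magic = fh.read(8)
        dialect = "internal" if magic.startswith(b"\x89HDF") else "EDF"
    if dialect.upper() == "EDF":
        return _read_edf(path)
    if dialect == "internal":
        return _read_h5(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def epoch_extract(
    session: RawSession,
    alignment: str,
    window: tuple[float, float],
) -> EpochSet:
    """Cut trials × channels × samples around S1 or around movement onset.

    Windows are half-open ``[start, end)`` in samples relative to the
    alignment time. Trials whose window exceeds the recording bounds
    are dropped (logged), never zero-padded.
    """
    start, end = window
    fs = session.sample_rate
    n_samp = int(round((end - start) * fs))
    if n_samp <= 0:
        raise ValueError(f"empty epoch window {window}")

    if alignment == "S1":
        align_times = session.events["s1_time"].to_numpy()
    elif alignment == "onset":
        if session.onsets is None:
            raise RuntimeError(
                "onset alignment requires detected/imputed onsets on the session"
            )
        merged = session.events.merge(session.onsets[["trial", "onset_time"]], on="trial", how="left")
        align_times = merged["onset_time"].to_numpy()
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    meta_rows = []
    slabs = []
    n_total = session.signal.shape[1]
    dropped = 0
    for i, (t0, (_, ev)) in enumerate(zip(align_times, session.events.iterrows())):
        if not np.isfinite(t0):
            dropped += 1
            continue
        lo = int(round((t0 + start) * fs))
        hi = lo + n_samp
        if lo < 0 or hi > n_total:
            dropped += 1
            continue
        slabs.append(session.signal[:, lo:hi])
        meta_rows.append({
            "orig_index": i,
            "trial": int(ev["trial"]),
            "block": int(ev["block"]),
            "movement": ev["movement"],
            "s1_time": float(ev["s1_time"]),
            "align_time": float(t0),
            "artifact": False,
        })
    if dropped:
        log.info("epoch_extract: dropped %d/%d trials outside recording bounds",
                 dropped, len(align_times))
    if not slabs:
        raise ValueError("no trial fits the requested window")
    meta = pd.DataFrame(meta_rows)
    meta["movement_class"] = pool_classes(meta["movement"])
    data = np.stack(slabs)
    return EpochSet(
        data=data, alignment=alignment, window=(start, end), sample_rate=fs,
        montage=session.montage, meta=meta,
    )
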