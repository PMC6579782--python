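"""EDF/EDF+ reading and writing for synthetic recordings.

Implements the European Data Format directly: 256-byte fixed header,
256 bytes of per-signal header fields, int16 little-endian samples, and an
"EDF Annotations" signal carrying the stimulus events as time-stamped
annotation lists (TALs).  The whole recording is stored as a single data
record, which keeps sample counts exact without padding.

Sample values are quantized to the signal's declared physical range over
the 16-bit digital range, so a round trip reproduces values within
``physical_range / 2**16`` (well inside the spec'd 2**15 bound).  Channel
names, sampling rate and event onsets/labels round-trip exactly.

The electrode geometry (which EDF cannot carry) travels in a JSON sidecar
``<path>.montage.json``; absent a sidecar, the reader rebuilds positions
from the standard 10-20 template by channel name.
"""

from __future__ import annotations

import os

import numpy as np

from .montage import Montage, standard_montage
from .synth import CONDITIONS, EventSequence, Recording

DIG_MIN, DIG_MAX = -32768, 32767
_ANN_LABEL = "EDF Annotations"


class EDFParseError(ValueError):
    """Malformed or truncated EDF file; message names the offending field."""


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _fmt_float(x: float, width: int = 8) -> str:
    for prec in range(10, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot represent {x} in {width} ascii chars")


def montage_sidecar_path(path) -> str:
    return str(path) + ".montage.json"


def write_edf(recording: Recording, path) -> None:
    """Write a recording as single-record EDF+C with annotation events."""
    data = recording.data
    n_ch, n_samples = data.shape
    rate = recording.rate
    duration = n_samples / rate
    dur_s = _fmt_float(duration)
    if abs(float(dur_s) * rate - n_samples) > 1e-6:
        raise ValueError(
            f"record duration {duration} not exactly representable in the "
            "8-character EDF duration field; resample or trim the recording"
        )

    # physical range: symmetric per channel, from the printed header strings
    # so that quantization and de-quantization use identical bounds
    pmins, pmaxs, scaled = [], [], []
    for ch in range(n_ch):
        amp = float(np.max(np.abs(data[ch]))) if n_samples else 1.0
        # 1% headroom so the printed (possibly rounded) bound still covers
        # every sample and nothing clips
        amp = max(amp * 1.01, 1e-3)
        pmax_s = _fmt_float(amp, 7)  # leave room for the sign in pmin
        pmax = float(pmax_s)
        pmins.append("-" + pmax_s if not pmax_s.startswith("-") else pmax_s)
        pmaxs.append(pmax_s)
        gain = (DIG_MAX - DIG_MIN) / (2 * pmax)
        dig = np.rint((data[ch] + pmax) * gain + DIG_MIN)
        scaled.append(np.clip(dig, DIG_MIN, DIG_MAX).astype("<i2"))

    # annotation payload: record-start TAL then one TAL per event
    tals = [b"+0\x14\x14\x00"]
    for onset, label in zip(recording.events.onsets, recording.events.labels):
        t = onset / rate
        tals.append(f"+{t:.6f}\x150.700\x14{label}\x14\x00".encode("ascii"))
    ann_payload = b"".join(tals)
    ann_spr = (len(ann_payload) + 1) // 2 + 8  # int16 "samples", small slack
    ann_bytes = ann_payload.ljust(2 * ann_spr, b"\x00")

    ns = n_ch + 1
    header_bytes = 256 * (ns + 1)
    head = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),  # local patient id (anonymous)
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(header_bytes), 8),
            _field("EDF+C", 44),
            _field("1", 8),  # number of data records
            _field(dur_s, 8),
            _field(str(ns), 4),
        ]
    )
    labels = [f"EEG {n}"[:16] for n in recording.montage.channel_names] + [_ANN_LABEL]
    sig = b"".join(_field(s, 16) for s in labels)
    sig += b"".join(_field("", 80) for _ in range(ns))  # transducer
    sig += b"".join(_field(s, 8) for s in ["uV"] * n_ch + [""])
    sig += b"".join(_field(s, 8) for s in pmins + ["-1"])
    sig += b"".join(_field(s, 8) for s in pmaxs + ["1"])
    sig += b"".join(_field(str(DIG_MIN), 8) for _ in range(ns))
    sig += b"".join(_field(str(DIG_MAX), 8) for _ in range(ns))
    sig += b"".join(_field("", 80) for _ in range(ns))  # prefiltering
    sig += b"".join(_field(str(s), 8) for s in [n_samples] * n_ch + [ann_spr])
    sig += b"".join(_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(head + sig)
        for ch in range(n_ch):
            fh.write(scaled[ch].tobytes())
        fh.write(ann_bytes)

    recording.montage.to_json(montage_sidecar_path(path))


def _parse_tals(raw: bytes, rate: float) -> tuple[np.ndarray, tuple[str, ...]]:
    onsets, labels = [], []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        try:
            stamp, *texts = tal.split(b"\x14")
            onset_s = float(stamp.split(b"\x15")[0])
        except (ValueError, IndexError) as exc:
            raise EDFParseError(f"malformed annotation TAL {tal!r}") from exc
        for text in texts:
            label = text.decode("utf-8", "replace")
            if label:
                onsets.append(int(round(onset_s * rate)))
                labels.append(label)
    order = np.argsort(onsets, kind="stable")
    return np.asarray(onsets, dtype=np.int64)[order], tuple(labels[i] for i in order)


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file written by :func:`write_edf` (or compatible)."""
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFParseError("file shorter than the 256-byte fixed header")

        def ascii_at(start, width, name):
            txt = head[start : start + width].decode("ascii", "replace").strip()
            return txt

        try:
            header_bytes = int(ascii_at(184, 8, "header bytes"))
            n_records = int(ascii_at(236, 8, "number of data records"))
            duration = float(ascii_at(244, 8, "record duration"))
            ns = int(ascii_at(252, 4, "number of signals"))
        except ValueError as exc:
            raise EDFParseError(f"non-numeric fixed-header field: {exc}") from exc
        if ns <= 0:
            raise EDFParseError(f"number of signals must be positive, got {ns}")

        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise EDFParseError("truncated per-signal header block")

        def column(offset, width):
            base = offset * ns
            return [
                sig_head[base + i * width : base + (i + 1) * width]
                .decode("ascii", "replace")
                .strip()
                for i in range(ns)
            ]

        labels = column(0, 16)
        try:
            pmin = [float(x) for x in column(16 + 80 + 8, 8)]
            pmax = [float(x) for x in column(16 + 80 + 16, 8)]
            dmin = [int(x) for x in column(16 + 80 + 24, 8)]
            dmax = [int(x) for x in column(16 + 80 + 32, 8)]
            spr = [int(x) for x in column(16 + 80 + 40 + 80, 8)]
        except ValueError as exc:
            raise EDFParseError(f"non-numeric signal-header field: {exc}") from exc

        record_bytes = 2 * sum(spr)
        expected = header_bytes + n_records * record_bytes
        if size < expected:
            raise EDFParseError(
                f"truncated data: file has {size} bytes, header promises {expected}"
            )

        payload = fh.read(n_records * record_bytes)

    eeg_idx = [i for i, lab in enumerate(labels) if lab != _ANN_LABEL]
    ann_idx = [i for i, lab in enumerate(labels) if lab == _ANN_LABEL]
    if not eeg_idx:
        raise EDFParseError("no EEG signals (every label is 'EDF Annotations')")
    n_eeg_samples = spr[eeg_idx[0]] * n_records
    if any(spr[i] != spr[eeg_idx[0]] for i in eeg_idx):
        raise EDFParseError("EEG signals disagree on samples-per-record")
    if duration <= 0:
        raise EDFParseError(f"record duration must be positive, got {duration}")
    rate = spr[eeg_idx[0]] / duration

    chunks = {i: [] for i in range(ns)}
    offsets = np.cumsum([0] + [2 * s for s in spr])
    for rec in range(n_records):
        base = rec * record_bytes
        for i in range(ns):
            chunks[i].append(payload[base + offsets[i] : base + offsets[i + 1]])

    data = np.empty((len(eeg_idx), n_eeg_samples))
    names = []
    for row, i in enumerate(eeg_idx):
        dig = np.frombuffer(b"".join(chunks[i]), dtype="<i2").astype(float)
        if dmax[i] == dmin[i]:
            raise EDFParseError(f"signal {labels[i]!r}: digital min equals max")
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[row] = (dig - dmin[i]) * gain + pmin[i]
        names.append(labels[i][4:] if labels[i].startswith("EEG ") else labels[i])

    if ann_idx:
        onsets, ann_labels = _parse_tals(b"".join(chunks[ann_idx[0]]), rate)
        keep = [k for k, lab in enumerate(ann_labels) if lab in CONDITIONS]
        events = EventSequence(onsets[keep], tuple(ann_labels[k] for k in keep))
    else:
        events = EventSequence(np.empty(0, dtype=np.int64), ())

    sidecar = montage_sidecar_path(path)
    if os.path.exists(sidecar):
        montage = Montage.from_json(sidecar)
        if tuple(montage.channel_names) != tuple(names):
            raise EDFParseError("montage sidecar channels do not match EDF labels")
    else:
        montage = standard_montage(tuple(names), _pick_mastoids(names))
    return Recording(data, rate, montage, events)


def _pick_mastoids(names: list[str]) -> tuple[str, str]:
    for pair in (("M1", "M2"), ("A1", "A2"), ("TP9", "TP10")):
        if pair[0] in names and pair[1] in names:
            return pair
    raise EDFParseError(
        "no montage sidecar and no recognizable mastoid pair among channels"
    )
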