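"""EDF (European Data Format) reading and writing plus plain-text annotations.

Reading goes through :mod:`mne`; writing uses a minimal in-repo EDF
writer (16-bit samples, one data record per second) sufficient for the
synthetic recordings this package produces.  Annotations travel in a
tab-separated companion file (`<stem>.annotations.tsv`) with columns
onset, offset, label, lobe, level — mirroring the plain-text summary
files that clinical EEG corpora ship next to their EDF recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import Annotation, EEGRecording

__all__ = ["read_edf", "write_edf", "read_annotations", "write_annotations"]


def _fixed(text, width):
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec, path):
    """Write a recording as EDF with 16-bit samples (one record per second)."""
    path = Path(path)
    rate = rec.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(round(rate))
    nch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / rate))
    data = np.zeros((nch, n_records * rate))
    data[:, : rec.n_samples] = rec.data

    pmin = float(np.floor(min(data.min(), -1.0)))
    pmax = float(np.ceil(max(data.max(), 1.0)))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * scale + dmin), dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(rec.subject, 80),
            _fixed("Startdate X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(256 * (nch + 1), 8),
            _fixed("", 44),
            _fixed(n_records, 8),
            _fixed(1, 8),
            _fixed(nch, 4),
        ]
    )
    fields = [
        (16, [name for name in rec.channel_names]),
        (80, ["EEG"] * nch),
        (8, ["uV"] * nch),
        (8, [f"{pmin:g}" for _ in range(nch)]),
        (8, [f"{pmax:g}" for _ in range(nch)]),
        (8, [str(dmin)] * nch),
        (8, [str(dmax)] * nch),
        (80, [""] * nch),
        (8, [str(rate)] * nch),
        (32, [""] * nch),
    ]
    sig_header = b"".join(
        b"".join(_fixed(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            chunk = digital[:, r * rate : (r + 1) * rate]
            fh.write(chunk.tobytes())
    return path


def read_edf(path):
    """Read an EDF file into an :class:`EEGRecording`.

    Channel names and the sampling rate come from the header; a
    companion `<stem>.annotations.tsv` file is loaded when present.
    Mixed per-channel sampling rates are unsupported.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise ValueError(f"EDF file {path} contains no channels")
    rates = {int(round(raw.info["sfreq"]))}
    if len(rates) != 1:
        raise ValueError("mixed per-channel sampling rates are unsupported")
    data = raw.get_data() * 1e6  # mne loads volts; recordings are in microvolts
    rec = EEGRecording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject=path.stem,
    )
    ann_path = path.parent / (path.stem + ".annotations.tsv")
    if ann_path.exists():
        rec.annotations = read_annotations(ann_path)
        for ann in rec.annotations:
            if ann.offset > rec.duration + 1e-6:
                raise ValueError(
                    f"annotation [{ann.onset}, {ann.offset}] outside record duration"
                )
    return rec


def write_annotations(annotations, path):
    lines = ["onset\toffset\tlabel\tlobe\tlevel"]
    for a in annotations:
        lines.append(
            f"{a.onset:g}\t{a.offset:g}\t{a.label}\t{a.lobe or '-'}\t{a.level or '-'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def read_annotations(path):
    out = []
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        onset, offset, label, lobe, level = line.split("\t")
        out.append(
            Annotation(
                onset=float(onset),
                offset=float(offset),
                label=label,
                lobe=None if lobe == "-" else lobe,
                level=None if level == "-" else level,
            )
        )
    return out
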