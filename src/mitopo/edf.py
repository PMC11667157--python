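"""Minimal EDF+C writer.

Writes continuous multichannel data plus event annotations in European
Data Format, enough for round-tripping synthetic recordings through
standard EDF readers.  One data record per second; samples are digitized
to 16-bit integers over a symmetric physical range.  Not a general EDF
authoring tool: no discontinuous records, sub-second record durations,
or per-channel sampling rates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["write_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    sampling_rate: float,
    channel_names: Sequence[str],
    events: Sequence[tuple[float, float, str]] = (),
    physical_range: tuple[float, float] | None = None,
) -> None:
    """Write ``samples`` ([channels x time], microvolts) as EDF+C.

    Parameters
    ----------
    events
        (onset_seconds, duration_seconds, description) triples stored in
        the annotations channel.
    physical_range
        (min, max) in microvolts for digitization; default is the
        symmetric range covering the data.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n_ch, n_time = samples.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    fs = float(sampling_rate)
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    spr = int(round(fs))  # samples per 1-s record
    n_records = int(np.ceil(n_time / spr))

    if physical_range is None:
        amp = max(1.0, float(np.max(np.abs(samples))) * 1.01)
        physical_range = (-amp, amp)
    pmin, pmax = physical_range
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_time] = samples
    digital = np.clip(
        np.round((padded - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    # Annotation channel: sized to hold the record timestamp plus any
    # events starting in that record.
    tal_records: list[bytes] = []
    for rec in range(n_records):
        tal = f"+{rec}\x14\x14\x00".encode("ascii")
        for onset, duration, desc in events:
            if rec <= onset < rec + 1:
                tal += (
                    f"+{onset:g}\x15{duration:g}\x14{desc}\x14\x00".encode("ascii")
                )
        tal_records.append(tal)
    ann_bytes = max(60, max(len(t) for t in tal_records))
    ann_bytes += ann_bytes % 2  # int16-sized channel
    ann_spr = ann_bytes // 2

    ns = n_ch + 1
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate 01-JAN-2000 X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * (ns + 1)), 8),
            _field("EDF+C", 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )

    labels = [str(c) for c in channel_names] + ["EDF Annotations"]
    transducers = [""] * ns
    dims = ["uV"] * n_ch + [""]
    pmins = [f"{pmin:.8g}"[:8] for _ in range(n_ch)] + ["-1"]
    pmaxs = [f"{pmax:.8g}"[:8] for _ in range(n_ch)] + ["1"]
    dmins = [str(dmin)] * ns
    dmaxs = [str(dmax)] * ns
    prefilter = [""] * ns
    sprs = [str(spr)] * n_ch + [str(ann_spr)]

    sig_header = b"".join(
        b"".join(_field(v, w) for v in values)
        for values, w in [
            (labels, 16),
            (transducers, 80),
            (dims, 8),
            (pmins, 8),
            (pmaxs, 8),
            (dmins, 8),
            (dmaxs, 8),
            (prefilter, 80),
            (sprs, 8),
            ([""] * ns, 32),
        ]
    )

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for rec in range(n_records):
            block = digital[:, rec * spr : (rec + 1) * spr]
            f.write(block.tobytes(order="C"))
            f.write(tal_records[rec].ljust(ann_bytes, b"\x00"))
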