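"""Segmentation of traces into fixed 90-s blocks with majority-vote labels.

Blocks are non-overlapping and consecutive; a trailing partial block is
dropped. The block label is the modal per-sample halter label; ties are broken
by the canonical precedence eating > rumination > other and counted through
the module logger. The fraction of samples agreeing with the winning label is
recorded as ``label_purity`` (>= 1/3 with three states).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .states import LABELS
from .synthdata import AccelTrace, LabelStream

logger = logging.getLogger(__name__)


@dataclass
class LabeledBlock:
    """One fixed-duration window of acceleration with a single truth label."""

    steer_id: str
    trial_id: str
    block_index: int
    samples: np.ndarray
    label: str
    label_purity: float


def segment_blocks(
    trace: AccelTrace,
    labels: LabelStream,
    block_seconds: float = 90.0,
    purity_threshold: float | None = None,
) -> list[LabeledBlock]:
    """Cut one steer's trace into labelled blocks.

    Parameters
    ----------
    purity_threshold
        Optional minimum majority fraction; blocks below it are discarded
        (off by default — all blocks are kept).
    """
    if len(trace.t) != len(labels.t) or not np.allclose(trace.t, labels.t):
        raise ValueError("trace and labels must share one sampling grid")
    if len(trace.t) < 2:
        return []  # too short even to infer the sampling grid
    fs = trace.sampling_rate
    n_per = block_seconds * fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("block_seconds x sampling_rate must be an integer")
    n_per = int(round(n_per))

    codes = np.array([LABELS.index(s) for s in labels.state], dtype=np.int64)
    n_blocks = len(trace.y) // n_per
    dropped = len(trace.y) - n_blocks * n_per
    if dropped:
        logger.debug("dropping %d trailing samples of %s", dropped, trace.steer_id)

    blocks: list[LabeledBlock] = []
    ties = 0
    for b in range(n_blocks):
        sl = slice(b * n_per, (b + 1) * n_per)
        counts = np.bincount(codes[sl], minlength=len(LABELS))
        top = counts.max()
        if (counts == top).sum() > 1:
            ties += 1
        winner = int(np.argmax(counts))  # first max -> canonical precedence
        purity = top / n_per
        if purity_threshold is not None and purity < purity_threshold:
            continue
        blocks.append(
            LabeledBlock(
                steer_id=trace.steer_id,
                trial_id=trace.trial_id,
                block_index=b,
                samples=trace.y[sl].copy(),
                label=LABELS[winner],
                label_purity=float(purity),
            )
        )
    if ties:
        logger.info(
            "%s: %d/%d blocks had tied majority votes (canonical precedence applied)",
            trace.steer_id,
            ties,
            n_blocks,
        )
    return blocks


def segment_dataset(
    traces: list[AccelTrace],
    labels: list[LabelStream],
    block_seconds: float = 90.0,
    purity_threshold: float | None = None,
) -> list[LabeledBlock]:
    """Segment every steer, preserving steer and time order."""
    by_id = {l.steer_id: l for l in labels}
    out: list[LabeledBlock] = []
    for trace in traces:
        out.extend(
            segment_blocks(trace, by_id[trace.steer_id], block_seconds, purity_threshold)
        )
    return out


def blocks_to_frame(blocks: list[LabeledBlock]) -> pd.DataFrame:
    """Block metadata table (no raw samples): one row per block."""
    return pd.DataFrame(
        {
            "steer_id": [b.steer_id for b in blocks],
            "trial_id": [b.trial_id for b in blocks],
            "block_index": [b.block_index for b in blocks],
            "label": [b.label for b in blocks],
            "purity": [b.label_purity for b in blocks],
        }
    )


def write_block_table(blocks: list[LabeledBlock], path: str | Path) -> None:
    blocks_to_frame(blocks).to_csv(path, index=False, float_format="%.6f")
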