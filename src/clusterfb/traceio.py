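"""File I/O: tidy trace CSVs and TIFF image stacks with masks."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .params import ParameterError
from .quantify import MaskedStack

__all__ = [
    "read_traces_csv",
    "write_traces_csv",
    "read_masked_stack",
    "write_masked_stack",
]

_TRACE_COLUMNS = ["cell_id", "field_id", "channel", "time_s", "value", "background"]


def read_traces_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy trace table; validates the required columns."""
    df = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"{path}: missing trace columns {sorted(missing)}")
    return df


def write_traces_csv(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(_TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ParameterError(f"trace table missing columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_masked_stack(stack_path: str | Path, mask_path: str | Path) -> MaskedStack:
    """Load a multi-page TIFF stack and a single-page TIFF mask."""
    frames = tifffile.imread(stack_path)
    if frames.ndim == 2:
        frames = frames[None]
    mask = tifffile.imread(mask_path)
    return MaskedStack(frames=np.asarray(frames, float), membrane_mask=mask > 0)


def write_masked_stack(
    stack: MaskedStack, stack_path: str | Path, mask_path: str | Path
) -> None:
    tifffile.imwrite(stack_path, stack.frames.astype(np.float32))
    tifffile.imwrite(mask_path, stack.membrane_mask.astype(np.uint8))
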