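"""Small format-conversion helpers: delimited tables, NIfTI, array containers.

Round trips are lossless where shapes permit: tables via TSV, volumes via
NIfTI (affine preserved) or ``.npy``. Used by the CLI ``convert`` command
and the pipeline writers.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import PreconditionError

__all__ = ["read_table", "write_table", "convert"]


def read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def convert(src, dst) -> None:
    """Convert between ``.nii/.nii.gz``, ``.npy`` and ``.tsv/.csv`` files.

    NIfTI -> npy drops the affine; npy -> NIfTI uses an identity affine;
    2-D arrays round-trip through delimited tables losslessly.
    """
    src, dst = Path(src), Path(dst)
    s, d = src.suffix.lower(), dst.suffix.lower()
    nii = {".nii", ".gz"}
    try:
        if s in nii:
            data = np.asarray(nib.load(str(src)).get_fdata())
        elif s == ".npy":
            data = np.load(src)
        elif s in {".tsv", ".csv"}:
            data = read_table(src).to_numpy()
        else:
            raise PreconditionError(f"unsupported input format {s!r}")
    except PreconditionError:
        raise
    except Exception as exc:
        raise PreconditionError(f"cannot parse {src}: {exc}") from exc
    if d in nii:
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=float), np.eye(4)), str(dst))
    elif d == ".npy":
        np.save(dst, data)
    elif d in {".tsv", ".csv"}:
        if data.ndim != 2:
            raise PreconditionError("only 2-D arrays can be written as tables")
        write_table(pd.DataFrame(data), dst)
    else:
        raise PreconditionError(f"unsupported output format {d!r}")
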