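"""Reading and writing allele-frequency time-series tables.

The on-disk format is a plain TSV with a mandatory ``time`` first column and
one column per locus; one row per sampled time, frequencies as decimal
fractions in ``[0, 1]``.  The first locus column is the focal locus by
convention.  Writing is deterministic (10 significant digits) so outputs are
diff-friendly and round-trip exactly at that precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .wf import TrajectorySet

__all__ = ["TimeSeriesParseError", "read_timeseries", "write_timeseries"]


class TimeSeriesParseError(ValueError):
    """A malformed time-series table (with the offending line where known)."""


def read_timeseries(path, focal: str | None = None) -> TrajectorySet:
    """Read a TSV of allele frequencies into a :class:`TrajectorySet`.

    Parameters
    ----------
    path
        File with header ``time<TAB>locus_a<TAB>locus_b...``.
    focal
        Column name to treat as the focal locus (moved to position 0);
        defaults to the first locus column.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TimeSeriesParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "time":
        raise TimeSeriesParseError(
            f"{path}: expected a 'time' column followed by locus columns, "
            f"got {list(df.columns)}"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise TimeSeriesParseError(f"{path}: ragged or non-numeric row at line {row + 2}")

    times = df["time"].to_numpy()
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise TimeSeriesParseError(
            f"{path}: times not strictly increasing at line {int(bad[0]) + 3}"
        )

    loci = list(df.columns[1:])
    if focal is not None:
        if focal not in loci:
            raise TimeSeriesParseError(f"{path}: no locus column named {focal!r}")
        loci = [focal] + [c for c in loci if c != focal]
    freqs = df[loci].to_numpy(dtype=float).T
    out_of_range = np.argwhere((freqs < 0) | (freqs > 1))
    if out_of_range.size:
        h, i = out_of_range[0]
        raise TimeSeriesParseError(
            f"{path}: frequency {freqs[h, i]} out of [0, 1] at line {i + 2}, "
            f"column {loci[h]!r}"
        )
    return TrajectorySet(times=times, freqs=freqs, locus_names=tuple(loci))


def write_timeseries(trajset: TrajectorySet, path) -> None:
    """Write a :class:`TrajectorySet` as a deterministic TSV.

    Frequencies are printed with ``%.10g`` (so exact 0 and 1 serialize as
    ``0`` and ``1``); times are printed as integers when integral.
    """
    names = trajset.locus_names or tuple(
        f"locus_{h}" for h in range(trajset.n_loci)
    )
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(names) + "\n")
        for i, t in enumerate(trajset.times):
            ti = int(t) if float(t).is_integer() else t
            row = "\t".join(f"{v:.10g}" for v in trajset.freqs[:, i])
            fh.write(f"{ti}\t{row}\n")
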