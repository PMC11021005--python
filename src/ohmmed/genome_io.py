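"""Window tracks: construction from genomic formats and annotated output.

All coordinates are 0-based half-open.  Chromosomes are tiled with
non-overlapping fixed-size windows; a trailing partial window is dropped
(not truncated) so every window has the same exposure, which both
emission families assume.  Windows failing quality rules are flagged
``kept=False`` and excluded from the sequence handed to the HMM; their
coordinates are retained so annotations map back to true positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowTrack",
    "gc_windows",
    "count_features_in_windows",
    "aggregate_interval_counts",
    "apply_exclusion_mask",
    "read_bed",
    "read_gff3_intervals",
    "write_track",
    "read_track",
    "write_annotation",
    "read_annotation",
]

TRACK_COLUMNS = ["chrom", "start", "end", "value", "kept"]


@dataclass
class WindowTrack:
    """Ordered fixed-size genomic windows with one value per window.

    windows : DataFrame with columns (chrom, start, end, value, kept),
        sorted by (chrom, start); non-overlapping; 0-based half-open.
    window_size : width in bp of every window.
    value_kind : "proportion" (reals) or "count" (non-negative integers).
    """

    windows: pd.DataFrame
    window_size: int
    value_kind: str = "proportion"

    def __post_init__(self):
        df = self.windows.reset_index(drop=True)
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track missing columns {missing}")
        widths = df["end"] - df["start"]
        if len(df) and np.any(widths != self.window_size):
            raise ValueError("all windows must have width == window_size")
        self.windows = df

    def __len__(self) -> int:
        return len(self.windows)

    def kept_values(self) -> np.ndarray:
        """The value sequence of kept windows, in genomic order — the
        contiguous sequence handed to the HMM."""
        v = self.windows.loc[self.windows["kept"], "value"].to_numpy()
        return v.astype(float)

    def kept_index(self) -> np.ndarray:
        return np.nonzero(self.windows["kept"].to_numpy())[0]

    def with_values(self, values, value_kind: str) -> "WindowTrack":
        df = self.windows.copy()
        df["value"] = values
        return WindowTrack(df, self.window_size, value_kind)


def _tile(chrom_sizes: dict, window_size: int) -> pd.DataFrame:
    rows = []
    for chrom, size in chrom_sizes.items():
        n = size // window_size  # trailing partial window dropped
        starts = np.arange(n, dtype=np.int64) * window_size
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + window_size}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def gc_windows(fasta_path, window_size: int, min_called_fraction: float = 0.9) -> WindowTrack:
    """GC-proportion track from a FASTA genome.

    Per window, "called" bases are A/C/G/T (case-insensitive; soft-masked
    lowercase counts as called); N and ambiguity codes are uncalled.  A
    window is kept iff called / window_size >= min_called_fraction, and
    its value is (G + C) / called.  Trailing partial windows are dropped.
    """
    from pyfaidx import Fasta

    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 0.0 < min_called_fraction <= 1.0:
        raise ValueError("min_called_fraction must lie in (0, 1]")
    genome = Fasta(str(fasta_path), rebuild=True)
    if not list(genome.keys()):
        raise ValueError(f"no sequences in {fasta_path}")
    rows = []
    for chrom in genome.keys():
        seq_len = len(genome[chrom])
        for start in range(0, seq_len - window_size + 1, window_size):
            seq = str(genome[chrom][start : start + window_size]).upper()
            called = sum(seq.count(b) for b in "ACGT")
            gc = seq.count("G") + seq.count("C")
            kept = called / window_size >= min_called_fraction
            value = gc / called if (kept and called) else np.nan
            rows.append((chrom, start, start + window_size, value, kept and called > 0))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return WindowTrack(df, window_size, "proportion")


def read_bed(path) -> pd.DataFrame:
    """Read BED3+ intervals (0-based half-open) into (chrom, start, end)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    _check_intervals(df, path)
    return df


def read_gff3_intervals(path) -> pd.DataFrame:
    """Read GFF3 features as (chrom, start, end) in 0-based half-open
    coordinates (GFF3 is 1-based inclusive on disk)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 3, 4], names=["chrom", "start", "end"], dtype={0: str},
    )
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    _check_intervals(df, path)
    return df


def _check_intervals(df: pd.DataFrame, source) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(f"malformed interval (end <= start) at record {bad[0] + 1} of {source}")


def _window_lookup(track: WindowTrack):
    """chrom -> (first row index, number of windows) for fixed-size tiles."""
    lookup = {}
    for chrom, grp in track.windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if len(starts) and (starts[0] != 0 or np.any(np.diff(starts) != track.window_size)):
            raise ValueError(f"windows on {chrom} are not a contiguous tiling from 0")
        lookup[chrom] = (grp.index[0], len(grp))
    return lookup


def count_features_in_windows(features: pd.DataFrame, track: WindowTrack) -> WindowTrack:
    """Count features overlapping each window by >= 1 bp.

    A feature increments *every* window its interval overlaps, so features
    spanning window boundaries count in multiple windows (features are
    not assigned uniquely).  ``features`` is a (chrom, start, end) frame
    from :func:`read_bed` or :func:`read_gff3_intervals`.
    """
    _check_intervals(features, "features")
    lookup = _window_lookup(track)
    ws = track.window_size
    counts = np.zeros(len(track), dtype=np.int64)
    for chrom, start, end in features[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in lookup:
            continue
        base, n = lookup[chrom]
        i0 = max(start // ws, 0)
        i1 = min((end - 1) // ws, n - 1)
        if i1 >= i0:
            counts[base + i0 : base + i1 + 1] += 1
    return track.with_values(counts, "count")


def aggregate_interval_counts(reads: pd.DataFrame, track: WindowTrack) -> WindowTrack:
    """Aggregate read intervals into windows by their 5' (leftmost) start.

    Each read is assigned to exactly one window — the one containing its
    start coordinate — so window totals sum to the number of reads that
    start inside the tiled region.
    """
    _check_intervals(reads, "reads")
    lookup = _window_lookup(track)
    ws = track.window_size
    counts = np.zeros(len(track), dtype=np.int64)
    for chrom, start in reads[["chrom", "start"]].itertuples(index=False):
        if chrom not in lookup:
            continue
        base, n = lookup[chrom]
        idx = start // ws
        if 0 <= idx < n:
            counts[base + idx] += 1
    return track.with_values(counts, "count")


def apply_exclusion_mask(track: WindowTrack, mask: pd.DataFrame) -> WindowTrack:
    """Mark windows overlapping any mask interval as ``kept=False``.

    Used e.g. to remove telomere- and centromere-adjacent windows, whose
    dynamics differ from the rest of the chromosome.  Idempotent.
    """
    df = track.windows.copy()
    for chrom, start, end in mask[["chrom", "start", "end"]].itertuples(index=False):
        hit = (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        df.loc[hit, "kept"] = False
    return WindowTrack(df, track.window_size, track.value_kind)


def write_track(track: WindowTrack, path) -> None:
    """TSV serialization with a header carrying window size and value kind."""
    with open(path, "w") as fh:
        fh.write(f"#window_size={track.window_size}\tvalue_kind={track.value_kind}\n")
        track.windows.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_track(path) -> WindowTrack:
    """Read a track written by :func:`write_track` (exact round trip)."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#window_size="):
            raise ValueError(f"missing track header in {path}")
        fields = dict(item.split("=", 1) for item in header[1:].split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    if df.empty:
        df = pd.DataFrame(columns=TRACK_COLUMNS)
        df = df.astype({"start": np.int64, "end": np.int64, "kept": bool})
    track = WindowTrack(df, int(fields["window_size"]), fields["value_kind"])
    if fields["value_kind"] == "count":
        kept = track.windows["kept"]
        vals = track.windows.loc[kept, "value"]
        if len(vals) and np.any(vals != np.floor(vals)):
            raise ValueError("count track contains non-integer values")
    return track


def write_annotation(track: WindowTrack, fit, path) -> None:
    """Annotated-track TSV: coordinates, value, hard state (1-based,
    ascending-mean order), per-state posterior probabilities and the
    position posterior mean.  Rows cover kept windows only, in order.
    """
    kept = track.windows[track.windows["kept"]].reset_index(drop=True)
    if len(kept) != fit.gamma_mean.shape[0]:
        raise ValueError(
            f"fit covers {fit.gamma_mean.shape[0]} positions but track has {len(kept)} kept windows"
        )
    out = kept[["chrom", "start", "end", "value"]].copy()
    out["state"] = fit.hard_assignment + 1
    for i in range(fit.K):
        out[f"p_state_{i + 1}"] = fit.gamma_mean[:, i]
    out["posterior_mean"] = fit.posterior_mean_track
    with open(path, "w") as fh:
        fh.write(f"#window_size={track.window_size}\tvalue_kind={track.value_kind}\tK={fit.K}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_annotation(path) -> pd.DataFrame:
    """Read an annotation TSV back into a DataFrame."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"missing annotation header in {path}")
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
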