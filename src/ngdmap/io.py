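"""File I/O: FASTQ streams, profile tables, time-course tables.

Reads are streamed in a single forward pass and never materialised;
profiles and time courses travel as plain TSV so fixtures stay
human-readable and diff-able.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator, TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reporters import RaceRead

if TYPE_CHECKING:  # pragma: no cover
    from .profile import CleavageProfile


def _open_text(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_reads(path: str | Path) -> Iterator[RaceRead]:
    """Stream reads from a (optionally gzipped) FASTQ file.

    Yields one :class:`RaceRead` per record in file order.  Truncated
    records or sequence/quality length mismatches raise ``ValueError``
    (from the underlying Biopython parser).
    """
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            qstr = "".join(chr(q + 33) for q in quals) if quals is not None else None
            yield RaceRead(id=rec.id, sequence=str(rec.seq), qualities=qstr)


def write_reads(reads: Iterable[RaceRead], path: str | Path) -> int:
    """Write reads to FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "w") as fh:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            quals = read.qualities or "I" * len(read.sequence)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


# ---------------------------------------------------------------------------
# profile tables

_PROFILE_COLUMNS = ["distance_upstream", "raw_count", "smoothed_value", "labelled_peak"]


def write_profile(profile: "CleavageProfile", path: str | Path) -> None:
    """Write a cleavage profile as TSV, one row per upstream position.

    Columns: distance_upstream, raw_count, smoothed_value (NA where no
    full smoothing window fits), labelled_peak (0/1).  Metadata travels
    in ``#``-prefixed header lines so the matching reader round-trips
    the profile losslessly.
    """
    smoothed = profile.smoothed
    if smoothed is None:
        smoothed = np.full(len(profile.counts), np.nan)
    labelled = profile.labelled
    if labelled is None:
        labelled = np.zeros(len(profile.counts), dtype=bool)
    frame = pd.DataFrame(
        {
            "distance_upstream": profile.distances,
            "raw_count": profile.counts,
            "smoothed_value": smoothed,
            "labelled_peak": labelled.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# reporter: {profile.reporter_name}\n")
        fh.write(f"# overflow: {profile.overflow}\n")
        fh.write(f"# downstream: {profile.n_downstream}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_profile(path: str | Path) -> "CleavageProfile":
    """Read a profile TSV written by :func:`write_profile`."""
    from .profile import CleavageProfile

    meta = {"reporter": "", "overflow": 0, "downstream": 0}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, sep="\t", na_values="NA")
    if list(frame.columns) != _PROFILE_COLUMNS:
        raise ValueError(f"unexpected profile columns in {path}: {list(frame.columns)}")
    smoothed = frame["smoothed_value"].to_numpy(dtype=float)
    if np.isnan(smoothed).all():
        smoothed_arr = None
    else:
        smoothed_arr = smoothed
    labelled = frame["labelled_peak"].to_numpy(dtype=int).astype(bool)
    return CleavageProfile(
        reporter_name=str(meta["reporter"]),
        counts=frame["raw_count"].to_numpy(dtype=int),
        smoothed=smoothed_arr,
        labelled=labelled if labelled.any() else None,
        overflow=int(meta["overflow"]),
        n_downstream=int(meta["downstream"]),
    )


# ---------------------------------------------------------------------------
# time-course tables

def read_decay_tsv(path: str | Path):
    """Load a decay time course: columns replicate, time_min, abundance."""
    from .kinetics import DecayCourse

    frame = pd.read_csv(path, sep="\t")
    return DecayCourse(frame)


def read_growth_tsv(path: str | Path):
    """Load growth curves: columns condition, replicate, time_h, od600.

    Returns a dict keyed by (condition, replicate) of
    :class:`~ngdmap.kinetics.GrowthCurve`.
    """
    from .kinetics import GrowthCurve

    frame = pd.read_csv(path, sep="\t")
    curves = {}
    for (condition, rep), grp in frame.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        curves[(condition, rep)] = GrowthCurve(
            times=grp["time_h"].to_numpy(dtype=float),
            od=grp["od600"].to_numpy(dtype=float),
            condition=str(condition),
            replicate=str(rep),
        )
    return curves


def read_trace_tsv(path: str | Path):
    """Load an A254 polysome trace: columns position, a254."""
    from .kinetics import PolysomeTrace

    frame = pd.read_csv(path, sep="\t")
    return PolysomeTrace(
        position=frame["position"].to_numpy(dtype=float),
        a254=frame["a254"].to_numpy(dtype=float),
    )


def write_fragments(fragments, reporter, path: str | Path) -> None:
    """Write mapped fragments as TSV (read_id, start, end3, mismatches,
    distance_upstream; distance is NA for stall-less reporters)."""
    rows = []
    stall = reporter.stall_start
    for frag in fragments:
        dist = stall - frag.end3 if stall is not None else None
        rows.append((frag.read_id, frag.start, frag.end3, frag.mismatches, dist))
    frame = pd.DataFrame(rows, columns=["read_id", "start", "end3", "mismatches", "distance_upstream"])
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_fragments(path: str | Path):
    """Read a fragment TSV written by :func:`write_fragments`."""
    from .mapping import AlignedFragment

    frame = pd.read_csv(path, sep="\t", na_values="NA")
    return [
        AlignedFragment(
            read_id=str(r.read_id), start=int(r.start), end3=int(r.end3), mismatches=int(r.mismatches)
        )
        for r in frame.itertuples(index=False)
    ]
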