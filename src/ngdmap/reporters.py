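"""Reporter constructs, reads and analysis configuration.

Everything positional in the pipeline is expressed in the frame of a single
reporter CDS (the canonical constructs are PGK1-based): a stall element —
a stem loop or a run of inhibitory codons — sits at a known 1-based
position, and the 5' amplification primer bounds every RACE fragment on
its 5' side.  All user-facing coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

_VALID_BASES = frozenset("ACGT")

#: Recognised stall-element classes.  ``none`` marks a control reporter
#: without a stall; positional operations that need the stall fail loudly.
STALL_TYPES = ("SL", "CGA12", "AAA12", "UUU12", "none")


@dataclass(frozen=True)
class ReporterSpec:
    """A reporter CDS with its stall element and amplification primer.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"PGK1-SL"``.
    sequence
        Nucleotide string over ``{A, C, G, T}`` (the reporter CDS);
        positions are 1-based.
    stall_start
        1-based position of the first nucleotide of the stall element,
        or ``None`` for a stall-less control.
    stall_type
        One of ``SL``, ``CGA12``, ``AAA12``, ``UUU12`` or ``none``.
    primer_start
        1-based position where the transcript-specific 5' primer anneals.
        Every mapped fragment starts at or after this position.
    """

    name: str
    sequence: str
    stall_start: Optional[int]
    stall_type: str
    primer_start: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reporter sequence is empty")
        seq = self.sequence.upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"reporter sequence contains invalid characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.stall_type not in STALL_TYPES:
            raise ValueError(f"unknown stall_type {self.stall_type!r}; expected one of {STALL_TYPES}")
        n = len(seq)
        if not 1 <= self.primer_start <= n:
            raise ValueError(f"primer_start {self.primer_start} outside sequence [1, {n}]")
        if self.stall_type == "none":
            if self.stall_start is not None:
                raise ValueError("stall_type='none' is incompatible with a stall_start")
        else:
            if self.stall_start is None:
                raise ValueError(f"stall_type={self.stall_type!r} requires stall_start")
            if not 1 <= self.stall_start <= n:
                raise ValueError(f"stall_start {self.stall_start} outside sequence [1, {n}]")
            if not self.primer_start < self.stall_start:
                raise ValueError(
                    f"primer_start {self.primer_start} must lie 5' of stall_start {self.stall_start}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_stall(self) -> bool:
        return self.stall_type != "none"

    def require_stall(self) -> int:
        """Return ``stall_start``, raising for stall-less controls."""
        if self.stall_start is None:
            raise ValueError(
                f"reporter {self.name!r} has no stall element; "
                "stall-relative analysis is undefined"
            )
        return self.stall_start


@dataclass(frozen=True)
class RaceRead:
    """One sequencing read from a 3'-adapter-ligated RACE library."""

    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality string length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


#: 3' adapter ligated to RNA 3' ends before reverse transcription
#: (the DNA portion of the adenylated oligo).
DEFAULT_ADAPTER = "CTGTAGGCACCATCAAT"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the trimming / mapping / profiling pipeline.

    Defaults follow conventional adapter-trimming practice and the
    published smoothing and labelling settings (5-point quadratic
    polynomial, 75th-percentile threshold).
    """

    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 6
    max_mismatch_frac: float = 0.1
    max_align_mismatches: int = 2
    min_fragment_length: int = 15
    smoothing_window: int = 5
    smoothing_order: int = 2
    peak_quantile: float = 0.75
    upstream_window: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.smoothing_window % 2 != 1:
            raise ValueError("smoothing_window must be odd")
        if not self.smoothing_order < self.smoothing_window:
            raise ValueError("smoothing_order must be < smoothing_window")
        if not 0.0 <= self.peak_quantile <= 1.0:
            raise ValueError("peak_quantile must lie in [0, 1]")
        if not 0.0 <= self.max_mismatch_frac < 1.0:
            raise ValueError("max_mismatch_frac must lie in [0, 1)")
        if self.min_overlap < 1 or self.min_fragment_length < 1:
            raise ValueError("min_overlap and min_fragment_length must be >= 1")
        if self.upstream_window < 1:
            raise ValueError("upstream_window must be >= 1")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a config from a flat TOML file; keyword overrides win."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **changes) -> "AnalysisConfig":
        return replace(self, **changes)


def load_reporter(path: str | Path) -> ReporterSpec:
    """Load a :class:`ReporterSpec` from a flat TOML file.

    The file declares ``name``, ``primer_start``, ``stall_type`` (and
    ``stall_start`` unless the type is ``none``), and either an inline
    ``sequence`` or a ``fasta`` path (resolved relative to the spec file;
    optional ``fasta_id`` selects a record, otherwise the first is used).
    """
    path = Path(path)
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    missing = {"name", "primer_start"} - set(data)
    if missing:
        raise ValueError(f"reporter spec {path} missing fields: {sorted(missing)}")
    if "sequence" in data:
        sequence = data["sequence"]
    elif "fasta" in data:
        from Bio import SeqIO

        fasta_path = path.parent / data["fasta"]
        wanted = data.get("fasta_id")
        sequence = None
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if wanted is None or rec.id == wanted:
                sequence = str(rec.seq)
                break
        if sequence is None:
            raise ValueError(f"no FASTA record {wanted!r} in {fasta_path}")
    else:
        raise ValueError(f"reporter spec {path} declares neither 'sequence' nor 'fasta'")
    return ReporterSpec(
        name=data["name"],
        sequence=sequence,
        stall_start=data.get("stall_start"),
        stall_type=data.get("stall_type", "none"),
        primer_start=data["primer_start"],
    )
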