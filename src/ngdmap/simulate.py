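"""Generative models of the wet-lab inputs.

Four simulators stand in for the experiments the pipeline analyses:

* endonucleolytic cleavage positions produced by ribosomes queued behind
  a stall (the fragment 3' ends a RACE library captures),
* adapter-bearing RACE reads with sequencing errors,
* exponential reporter-decay time courses after transcriptional shutoff,
* logistic OD600 growth curves with condition-dependent lag shifts.

The cleavage model encodes the geometry of a collided-ribosome queue:
the stalled lead ribosome protects ``lead_footprint`` nucleotides (15 by
default) 5' of the stall, each trailing ribosome protects
``trail_footprint`` more (30 by default).  Cleavage at the upstream
boundary of a queued ribosome therefore produces 3' ends at

    distance_upstream(k) = lead + (k - 1) * trail,   k = 1..n_ribosomes

in *static* mode (a persistent queue, 30-nt periodicity), while
*iterative* mode models cleavage–runoff cycles in which the queue
re-forms at each new 3' end, so successive sites recede by
``lead + trail`` (45 nt with defaults) per cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .reporters import DEFAULT_ADAPTER, RaceRead, ReporterSpec

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class QueueModel:
    """Parameters of the queued-ribosome cleavage model.

    ``keep_all`` is a diagnostic switch: instead of keeping only the
    most-3' fired boundary per event, every fired boundary is emitted,
    which exposes the full queue geometry in one library.
    """

    lead_footprint: int = 15
    trail_footprint: int = 30
    n_ribosomes: int = 4
    mode: str = "static"
    cleavage_prob: float = 1.0
    n_events: int = 1000
    seed: int = 0
    jitter: int = 0
    keep_all: bool = False

    def __post_init__(self) -> None:
        if self.lead_footprint <= 0 or self.trail_footprint <= 0:
            raise ValueError("footprints must be positive")
        if not 0.0 <= self.cleavage_prob <= 1.0:
            raise ValueError("cleavage_prob must lie in [0, 1]")
        if self.n_ribosomes < 1:
            raise ValueError("n_ribosomes must be >= 1")
        if self.mode not in ("static", "iterative"):
            raise ValueError(f"mode must be 'static' or 'iterative', got {self.mode!r}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def simulate_cleavage_sites(model: QueueModel, reporter: ReporterSpec) -> list[int]:
    """Draw fragment 3'-end coordinates (1-based reporter positions).

    Static mode: for each event every queue boundary fires independently
    with ``cleavage_prob``; the most-3' fired boundary wins (all fired
    boundaries are kept when ``model.keep_all``).  Iterative mode: one
    cleavage per cycle at ``lead + trail`` upstream of the current 3'
    end; the queue then re-forms there, so sites recede by 45 nt per
    cycle with default footprints.  Events whose site would fall before
    position 1 are discarded with a logged count.  Deterministic given
    the seed.
    """
    stall = reporter.require_stall()
    rng = np.random.default_rng(model.seed)
    sites: list[int] = []
    discarded = 0
    jit = model.jitter

    def emit(distance: int) -> None:
        nonlocal discarded
        if jit:
            distance += int(rng.integers(-jit, jit + 1))
        pos = stall - distance
        if pos < 1 or distance < 1:
            discarded += 1
        else:
            sites.append(pos)

    if model.mode == "static":
        boundaries = model.lead_footprint + model.trail_footprint * np.arange(model.n_ribosomes)
        for _ in range(model.n_events):
            fired = rng.random(model.n_ribosomes) < model.cleavage_prob
            if not fired.any():
                continue
            if model.keep_all:
                for d in boundaries[fired]:
                    emit(int(d))
            else:
                emit(int(boundaries[fired][0]))  # most-3' fired boundary
    else:  # iterative
        step = model.lead_footprint + model.trail_footprint
        distance = 0
        for _ in range(model.n_events):
            if rng.random() >= model.cleavage_prob:
                continue
            nxt = distance + step
            if stall - nxt < 1:
                # molecule fully consumed; a fresh one enters the cycle
                discarded += 1
                distance = 0
                continue
            distance = nxt
            emit(distance)

    if discarded:
        logger.info("simulate_cleavage_sites: discarded %d out-of-range events", discarded)
    return sites


def capturable_sites(
    sites: Sequence[int], reporter: ReporterSpec, min_length: int = 1
) -> list[int]:
    """Restrict cleavage sites to those a RACE library can capture.

    Amplification needs the transcript-specific primer inside the
    fragment, so 3' ends 5' of ``primer_start`` are invisible to the
    library (the iterative cleavage chain eventually walks past it).
    ``min_length`` additionally drops fragments shorter than the
    downstream aligner's minimum mappable length.
    """
    cutoff = reporter.primer_start + min_length - 1
    return [s for s in sites if s >= cutoff]


@dataclass(frozen=True)
class ReadSimParams:
    """Read-level details of the simulated RACE library."""

    read_length: int = 50
    per_base_error_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER
    frac_no_adapter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must lie in [0, 1)")
        if not 0.0 <= self.frac_no_adapter <= 1.0:
            raise ValueError("frac_no_adapter must lie in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


def synthesize_reads(
    sites: Sequence[int], reporter: ReporterSpec, params: ReadSimParams
) -> Iterator[RaceRead]:
    """Generate one RACE read per cleavage site.

    Each read is the reporter subsequence from the primer to the site,
    with the adapter appended 3' (except for the no-adapter fraction),
    kept to the read budget by truncating on the 5' side — the 3' end,
    which carries the positional signal, is always preserved — and
    finally perturbed by uniform point errors.
    """
    rng = np.random.default_rng(params.seed)
    primer = reporter.primer_start
    seq = reporter.sequence
    for i, site in enumerate(sites):
        if site < primer:
            raise ValueError(f"site {site} lies 5' of the primer at {primer}")
        fragment = seq[primer - 1 : site]
        with_adapter = rng.random() >= params.frac_no_adapter
        full = fragment + (params.adapter if with_adapter else "")
        read_seq = full[-params.read_length :]
        if params.per_base_error_rate > 0:
            arr = np.frombuffer(read_seq.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(arr.size) < params.per_base_error_rate)
            for j in hits:
                choices = _BASES[_BASES != arr[j]]
                arr[j] = choices[rng.integers(3)]
            read_seq = arr.tobytes().decode()
        yield RaceRead(id=f"sim_{i}|site={site}", sequence=read_seq, qualities="I" * len(read_seq))


def simulate_decay_course(
    t_half: float,
    times: Sequence[float],
    noise_cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
):
    """Simulate a transcriptional-shutoff decay course.

    Abundance follows ``exp(-ln2 * t / t_half)`` (normalised to the
    pre-shutoff level), perturbed by multiplicative lognormal noise of
    coefficient of variation ``noise_cv`` independently per replicate
    and timepoint.  Lognormal noise keeps abundances positive, matching
    the support of a blot quantification.
    """
    from .kinetics import DecayCourse

    if t_half <= 0:
        raise ValueError("t_half must be positive")
    t = np.asarray(times, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("times must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    clean = np.exp(-math.log(2) * t / t_half)
    rows = []
    for rep in range(n_reps):
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1 + noise_cv**2))
            noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=t.size)
        else:
            noise = np.ones(t.size)
        for ti, ab in zip(t, clean * noise):
            rows.append((f"rep{rep + 1}", ti, ab))
    import pandas as pd

    return DecayCourse(pd.DataFrame(rows, columns=["replicate", "time_min", "abundance"]))


def simulate_growth_curve(
    max_rate: float = 0.6,
    midpoint: float = 9.0,
    carrying_od: float = 1.2,
    lag_shift: float = 0.0,
    noise_sd: float = 0.0,
    times: Optional[Sequence[float]] = None,
    seed: int = 0,
    baseline_od: float = 0.05,
    condition: str = "sim",
    replicate: str = "rep1",
):
    """Simulate a microplate OD600 growth curve.

    A logistic sigmoid ``baseline + K / (1 + exp(-r (t - m - lag)))``
    with rate ``max_rate`` (per hour), inflection at ``midpoint +
    lag_shift`` hours and carrying OD ``K``, plus additive Gaussian
    noise clipped at zero.  Default sampling mirrors a plate reader:
    every 10 minutes over 24 h.
    """
    from .kinetics import GrowthCurve

    if carrying_od <= 0:
        raise ValueError("carrying_od must be positive")
    if times is None:
        times = np.arange(0.0, 24.0 + 1e-9, 1.0 / 6.0)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    od = baseline_od + carrying_od / (1.0 + np.exp(-max_rate * (t - midpoint - lag_shift)))
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=t.size)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(times=t, od=od, condition=condition, replicate=replicate)


def synthetic_reporter(
    name: str = "PGK1-SL",
    length: int = 1500,
    stall_start: Optional[int] = 1040,
    stall_type: str = "SL",
    primer_start: int = 585,
    seed: int = 0,
) -> ReporterSpec:
    """Build a synthetic stand-in for a stalling reporter CDS.

    The backbone is a seeded random sequence (a real PGK1 CDS is not
    bundled); codon-run stall types substitute the literal 36-nt run at
    the stall position, ``SL`` substitutes an 18-bp stem / 8-nt loop
    hairpin.  Positional defaults match the canonical constructs:
    stem loop at 1040, codon runs at 950, primer at 585.
    """
    rng = np.random.default_rng(seed)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    if stall_type != "none" and stall_start is not None:
        if stall_type in ("CGA12", "AAA12", "UUU12"):
            unit = {"CGA12": "CGA", "AAA12": "AAA", "UUU12": "TTT"}[stall_type]
            element = unit * 12
        elif stall_type == "SL":
            stem = "".join("ACGT"[i] for i in rng.integers(0, 4, size=18))
            loop = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8))
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            element = stem + loop + "".join(comp[b] for b in reversed(stem))
        else:
            raise ValueError(f"unknown stall_type {stall_type!r}")
        i0 = stall_start - 1
        if i0 + len(element) > length:
            raise ValueError("stall element extends past the reporter end")
        seq[i0 : i0 + len(element)] = element
    return ReporterSpec(
        name=name,
        sequence="".join(seq),
        stall_start=stall_start if stall_type != "none" else None,
        stall_type=stall_type,
        primer_start=primer_start,
    )
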