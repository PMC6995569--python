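"""End-to-end pipeline driver: scale space -> NNMF -> picking -> segmentation."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import CandidateRejected, EllipseFitError, NMFPickError
from .factorization import ChannelPair, nnmf, reconstruct_channels
from .micrograph import Micrograph, invert, normalize
from .picking import BinaryPair, RegionCandidate, pick_candidates
from .scale_space import build_feature_matrix
from .segmentation import ParticleRecord, segment_candidate

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Particle records plus the intermediates useful for inspection."""

    particles: list[ParticleRecord]
    candidates: list[RegionCandidate] = field(default_factory=list)
    channels: ChannelPair | None = None
    binaries: BinaryPair | None = None
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    micrograph: Micrograph, config: PipelineConfig | None = None
) -> list[ParticleRecord]:
    """Run the three phases and return the accepted, segmented particles."""
    return run_pipeline_full(micrograph, config).particles


def run_pipeline_full(
    micrograph: Micrograph, config: PipelineConfig | None = None
) -> PipelineResult:
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    mic = normalize(micrograph)
    if mic.degenerate:
        logger.warning("constant micrograph; nothing to pick")
        return PipelineResult(particles=[], timings=timings)
    if config.invert:
        mic = invert(mic)

    try:
        fm = build_feature_matrix(mic, config.scale_space)
    except NMFPickError as exc:
        raise type(exc)(f"scale_space stage: {exc}") from exc
    timings["scale_space"] = time.perf_counter() - t0
    logger.info(
        "scale space: %d rows of %d px in %.2fs",
        fm.n_rows, fm.values.shape[1], timings["scale_space"],
    )

    t0 = time.perf_counter()
    try:
        factors = nnmf(fm, config.nnmf)
        channels = reconstruct_channels(factors, fm.row_meta, mic.shape)
    except NMFPickError as exc:
        raise type(exc)(f"factorization stage: {exc}") from exc
    timings["factorization"] = time.perf_counter() - t0
    logger.info(
        "nnmf: %d iterations, objective %.4g -> %.4g in %.2fs",
        len(factors.objective_trace) - 1,
        factors.objective_trace[0],
        factors.objective_trace[-1],
        timings["factorization"],
    )

    t0 = time.perf_counter()
    try:
        candidates, binaries = pick_candidates(
            channels.W1, channels.W2, config.picking
        )
    except NMFPickError as exc:
        raise type(exc)(f"picking stage: {exc}") from exc
    timings["picking"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    particles: list[ParticleRecord] = []
    if binaries is not None:
        for cand in candidates:
            if not cand.accepted:
                continue
            try:
                particles.append(
                    segment_candidate(cand, binaries.B1, config.segmentation)
                )
            except (CandidateRejected, EllipseFitError) as exc:
                logger.debug("candidate %d dropped in segmentation: %s", cand.label, exc)
    timings["segmentation"] = time.perf_counter() - t0
    logger.info(
        "pipeline: %d candidates -> %d particles (%.2fs picking, %.2fs segmentation)",
        len(candidates), len(particles), timings["picking"], timings["segmentation"],
    )
    return PipelineResult(
        particles=particles,
        candidates=candidates,
        channels=channels,
        binaries=binaries,
        timings=timings,
    )
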