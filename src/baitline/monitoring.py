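"""Population-index computations for chewcard and leg-hold-trap surveys.

A chewcard line yields the CCI (percent of cards interfered with over the
session) and its arcsine-square-root transform tCCI, which de-saturates
the index when pre-control interference approaches 100%. Control
effectiveness is the percentage change in tCCI per line, combined across
lines with card-count weights; block-level display bounds are produced by
back-transforming the weighted mean pre/post levels +-1 SE, which makes
the reported errors asymmetric. Trapping yields the RTCI — possum
captures per 100 available trap-nights, with half a trap-night deducted
for every non-target capture or sprung trap. A small QA helper reports
the signed percent deviation of assayed toxin loading from its
specification.

Species (possum, rat, other) are processed fully independently; "other"
interference is retained in the CSV schemas for QA but carries no
analysis of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import weighted_mean_se

__all__ = [
    "ChewcardRecord",
    "TrapNightRecord",
    "LineIndex",
    "BlockReduction",
    "UndefinedReductionError",
    "arcsine_index",
    "back_transform",
    "line_cci",
    "line_indices",
    "line_reduction",
    "block_reduction",
    "rtci",
    "toxin_loading_deviation",
    "read_chewcards",
    "write_chewcards",
    "read_traps",
    "write_traps",
    "line_indices_frame",
    "block_reduction_frame",
]

SESSIONS = ("pre", "post")
TRAP_OUTCOMES = ("possum_capture", "nontarget_or_sprung", "empty")
ANALYSIS_SPECIES = ("possum", "rat")
CHEWCARD_COLUMNS = [
    "card_id", "line_id", "block_id", "session", "possum", "rat", "other", "nights",
]
TRAP_COLUMNS = ["trap_id", "line_id", "block_id", "night", "outcome"]


class UndefinedReductionError(ValueError):
    """Raised when a per-line reduction is undefined (pre-control tCCI = 0)."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class ChewcardRecord:
    card_id: str
    line_id: str
    block_id: str
    session: str  # "pre" or "post"
    species_flags: dict  # species -> bool (interfered over the session)
    nights: int = 6

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.nights < 1:
            raise ValueError("nights must be >= 1")


@dataclass
class TrapNightRecord:
    trap_id: str
    line_id: str
    block_id: str
    night: int
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in TRAP_OUTCOMES:
            raise ValueError(f"outcome must be one of {TRAP_OUTCOMES}")


@dataclass
class LineIndex:
    line_id: str
    species: str
    n_cards: int
    cci: float  # percent in [0, 100]
    tcci: float  # degrees in [0, 90]


@dataclass
class BlockReduction:
    block_id: str
    species: str
    per_line_reduction: list
    weights: list  # pre-session card counts
    mean_reduction: float
    se_lower: float
    se_upper: float
    n_lines: int
    n_cards: int
    excluded_lines: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# index arithmetic
# ---------------------------------------------------------------------------


def arcsine_index(p: float) -> float:
    """arcsin(sqrt(p)) in degrees; the variance-stabilising transform that
    linearises a saturating detection index."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {p}")
    return math.degrees(math.asin(math.sqrt(p)))


def back_transform(tcci_deg: float) -> float:
    """Inverse of :func:`arcsine_index`: sin^2(t) as a proportion."""
    if not 0.0 <= tcci_deg <= 90.0:
        raise ValueError(f"tCCI must be in [0, 90] degrees, got {tcci_deg}")
    return math.sin(math.radians(tcci_deg)) ** 2


def line_cci(records, species: str) -> LineIndex:
    """CCI and tCCI for the chewcard records of a single line/session."""
    records = list(records)
    if not records:
        raise ValueError("cannot compute a line index from zero cards")
    line_ids = {r.line_id for r in records}
    if len(line_ids) != 1:
        raise ValueError(f"records span multiple lines: {sorted(line_ids)}")
    if len({r.session for r in records}) != 1:
        raise ValueError("records span multiple sessions")
    n = len(records)
    hits = sum(bool(r.species_flags.get(species, False)) for r in records)
    cci = 100.0 * hits / n
    return LineIndex(
        line_id=records[0].line_id,
        species=species,
        n_cards=n,
        cci=cci,
        tcci=arcsine_index(cci / 100.0),
    )


def line_indices(records, species: str, session: str) -> list:
    """Per-line indices for one species/session, grouped by line_id."""
    by_line: dict[str, list] = {}
    for r in records:
        if r.session == session:
            by_line.setdefault(r.line_id, []).append(r)
    return [line_cci(v, species) for _, v in sorted(by_line.items())]


def line_reduction(pre: LineIndex, post: LineIndex) -> float:
    """Percentage change in tCCI, 100 * (pre - post) / pre.

    Scale-invariant (identical in degrees or radians). A pre-control tCCI
    of zero leaves the reduction undefined; such lines are excluded from
    block means and reported via :class:`BlockReduction.excluded_lines`.
    """
    if pre.line_id != post.line_id:
        raise ValueError("pre/post indices are for different lines")
    if pre.tcci == 0.0:
        raise UndefinedReductionError(
            f"line {pre.line_id}: pre-control tCCI is zero; reduction undefined"
        )
    return 100.0 * (pre.tcci - post.tcci) / pre.tcci


def block_reduction(pre_lines, post_lines, block_id: str, species: str) -> BlockReduction:
    """Card-weighted block-level reduction with asymmetric display bounds.

    The point estimate is the mean of per-line tCCI reductions weighted by
    pre-session card counts. Display bounds come from the weighted mean
    pre and post tCCI levels +-1 SE: the upper reduction bound pairs the
    upper pre level with the lower post level and vice versa, which (after
    back-transforming the levels to the CCI scale for reporting) yields
    asymmetric errors about the mean.
    """
    post_by_id = {li.line_id: li for li in post_lines}
    usable_pre, usable_post, excluded = [], [], []
    for pre in pre_lines:
        if pre.line_id not in post_by_id:
            raise ValueError(f"line {pre.line_id} has no post-control index")
        if pre.tcci == 0.0:
            excluded.append(pre.line_id)
        else:
            usable_pre.append(pre)
            usable_post.append(post_by_id[pre.line_id])
    if len(usable_pre) < 2:
        raise ValueError(
            f"block {block_id}: fewer than two usable lines for {species} "
            f"({len(usable_pre)} usable, {len(excluded)} excluded)"
        )
    reductions = np.array(
        [line_reduction(p, q) for p, q in zip(usable_pre, usable_post)]
    )
    weights = np.array([p.n_cards for p in usable_pre], dtype=float)
    mean, _se = weighted_mean_se(reductions, weights)

    t_pre, se_pre = weighted_mean_se([p.tcci for p in usable_pre], weights)
    t_post, se_post = weighted_mean_se([q.tcci for q in usable_post], weights)
    se_pre = 0.0 if math.isnan(se_pre) else se_pre
    se_post = 0.0 if math.isnan(se_post) else se_post
    hi_pre, lo_pre = min(t_pre + se_pre, 90.0), max(t_pre - se_pre, 1e-9)
    hi_post, lo_post = min(t_post + se_post, 90.0), max(t_post - se_post, 0.0)
    red_hi = 100.0 * (1.0 - lo_post / hi_pre)
    red_lo = 100.0 * (1.0 - hi_post / lo_pre)
    return BlockReduction(
        block_id=block_id,
        species=species,
        per_line_reduction=[float(r) for r in reductions],
        weights=[int(w) for w in weights],
        mean_reduction=mean,
        se_lower=max(mean - red_lo, 0.0),
        se_upper=max(red_hi - mean, 0.0),
        n_lines=len(usable_pre),
        n_cards=int(weights.sum()),
        excluded_lines=excluded,
    )


# ---------------------------------------------------------------------------
# trapping index
# ---------------------------------------------------------------------------


def rtci(records) -> float:
    """Residual Trap Catch Index: possum captures per 100 available
    trap-nights, deducting half a trap-night per non-target/sprung event."""
    records = list(records)
    if not records:
        raise ValueError("RTCI needs at least one trap-night")
    total = len(records)
    captures = sum(r.outcome == "possum_capture" for r in records)
    penalized = sum(r.outcome == "nontarget_or_sprung" for r in records)
    denom = total - 0.5 * penalized
    if denom <= 0:
        raise ValueError("corrected trap-night denominator is not positive")
    return 100.0 * captures / denom


# ---------------------------------------------------------------------------
# bait QA
# ---------------------------------------------------------------------------


def toxin_loading_deviation(assay_pct: float, spec_pct: float) -> int:
    """Signed percent deviation of assayed toxin loading from specification,
    rounded to a whole percent (half away from zero)."""
    if spec_pct <= 0:
        raise ValueError("specified loading must be positive")
    dev = 100.0 * (assay_pct - spec_pct) / spec_pct
    # half-away-from-zero, with a guard against representation error at
    # exact halves (e.g. a 7.5% deviation printed as 8)
    return int(math.copysign(math.floor(abs(dev) + 0.5 + 1e-9), dev))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def write_chewcards(records, path) -> None:
    rows = [
        {
            "card_id": r.card_id,
            "line_id": r.line_id,
            "block_id": r.block_id,
            "session": r.session,
            "possum": int(bool(r.species_flags.get("possum", False))),
            "rat": int(bool(r.species_flags.get("rat", False))),
            "other": int(bool(r.species_flags.get("other", False))),
            "nights": r.nights,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CHEWCARD_COLUMNS).to_csv(path, index=False)


def read_chewcards(path) -> list:
    df = pd.read_csv(path)
    missing = set(CHEWCARD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chewcard CSV missing columns: {sorted(missing)}")
    seen = set()
    records = []
    for row in df.itertuples(index=False):
        key = (row.card_id, row.session)
        if key in seen:
            raise ValueError(f"duplicate card {row.card_id!r} in session {row.session!r}")
        seen.add(key)
        records.append(
            ChewcardRecord(
                card_id=str(row.card_id),
                line_id=str(row.line_id),
                block_id=str(row.block_id),
                session=str(row.session),
                species_flags={
                    "possum": bool(row.possum),
                    "rat": bool(row.rat),
                    "other": bool(row.other),
                },
                nights=int(row.nights),
            )
        )
    return records


def write_traps(records, path) -> None:
    rows = [
        {
            "trap_id": r.trap_id,
            "line_id": r.line_id,
            "block_id": r.block_id,
            "night": r.night,
            "outcome": r.outcome,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TRAP_COLUMNS).to_csv(path, index=False)


def read_traps(path) -> list:
    df = pd.read_csv(path)
    missing = set(TRAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trap CSV missing columns: {sorted(missing)}")
    return [
        TrapNightRecord(
            trap_id=str(r.trap_id),
            line_id=str(r.line_id),
            block_id=str(r.block_id),
            night=int(r.night),
            outcome=str(r.outcome),
        )
        for r in df.itertuples(index=False)
    ]


def line_indices_frame(records, species_list=ANALYSIS_SPECIES) -> pd.DataFrame:
    """Tidy per-line index table over blocks, sessions and species."""
    rows = []
    by_block: dict[str, list] = {}
    for r in records:
        by_block.setdefault(r.block_id, []).append(r)
    for block_id in sorted(by_block):
        for session in SESSIONS:
            for sp in species_list:
                for li in line_indices(by_block[block_id], sp, session):
                    rows.append(
                        {
                            "block_id": block_id,
                            "session": session,
                            "species": sp,
                            "line_id": li.line_id,
                            "n_cards": li.n_cards,
                            "cci": li.cci,
                            "tcci": li.tcci,
                        }
                    )
    return pd.DataFrame(rows)


def block_reduction_frame(records, species_list=ANALYSIS_SPECIES) -> pd.DataFrame:
    """Per-block reduction table (mean, asymmetric SEs, line/card counts)."""
    rows = []
    by_block: dict[str, list] = {}
    for r in records:
        by_block.setdefault(r.block_id, []).append(r)
    for block_id in sorted(by_block):
        recs = by_block[block_id]
        for sp in species_list:
            br = block_reduction(
                line_indices(recs, sp, "pre"),
                line_indices(recs, sp, "post"),
                block_id,
                sp,
            )
            rows.append(
                {
                    "block_id": block_id,
                    "species": sp,
                    "mean_reduction": br.mean_reduction,
                    "se_lower": br.se_lower,
                    "se_upper": br.se_upper,
                    "n_lines": br.n_lines,
                    "n_cards": br.n_cards,
                    "excluded_lines": ";".join(br.excluded_lines),
                }
            )
    return pd.DataFrame(rows)
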