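"""De novo read-out of an oligomer sequence from an MS/MS peak list.

The reader exploits the two complementary fragment-ladder series produced
by urethane-bond cleavage.  It anchors each series at its first rung (the
smallest start-containing and stop-containing fragments), then walks each
ladder one rung at a time: from the current matched peak ``m`` it tests
``m + unit_mass(b)`` for every building block ``b`` against the peak list
within an absolute mass tolerance; a unique hit extends the walk by one
assigned position.  The left walk reads the sequence first-to-last, the
right walk last-to-first, and the two are merged position by position —
positions claimed by both directions must agree exactly.

A single missing rung is bridged by testing two-unit jumps
(``m + u(b1) + u(b2)``); the bridge typically leaves the *order* of the
two spanned positions ambiguous (both orders give the same sum), which the
opposite walk resolves.  The same pair-jump recovers a missing first rung,
so a spectrum lacking its smallest fragment peak can still be read — the
behaviour demonstrated for the recovered octamer in read experiments.

Ambiguities are surfaced, never resolved by intensity heuristics: the
method's guarantee rests on the alphabet's unit masses being spaced more
than twice the tolerance apart (checked at read time).

Complexity of a read is O(L * B * log P) for length L, alphabet size B and
P peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet
from .errors import AnchorMissingError, ConfigError
from .massmodel import MassModel, oligomer_mass
from .peaks import PeakList

log = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"


@dataclass(frozen=True)
class ReaderConfig:
    """Peak-acceptance and merging policy.

    ``tolerance`` is an absolute m/z window in Da (the instrument
    acceptance rule used for MALDI-TOF/TOF read-out: 0.02 Da, S/N > 5);
    set ``ppm=True`` to interpret it as parts-per-million instead.
    ``max_missing_per_position`` missing rungs are bridged per walk step
    (only 0 or 1 supported).
    """

    tolerance: float = 0.02
    snr_min: float = 5.0
    require_both_anchors: bool = True
    max_missing_per_position: int = 1
    ppm: bool = False

    def __post_init__(self):
        if not self.tolerance > 0:
            raise ConfigError("tolerance must be > 0")
        if self.snr_min < 0:
            raise ConfigError("snr_min must be >= 0")
        if self.max_missing_per_position not in (0, 1):
            raise ConfigError("max_missing_per_position must be 0 or 1")

    def tol_at(self, mz: float) -> float:
        return self.tolerance * mz * 1e-6 if self.ppm else self.tolerance


@dataclass(frozen=True)
class Anchor:
    """A peak matching a first-rung fragment mass, with its candidate labels."""

    mz: float
    labels: tuple[str, ...]


@dataclass
class WalkResult:
    """Partial assignment from one directional ladder walk.

    ``candidates`` maps 1-based sequence positions to label candidate sets;
    ``gap_at`` is the position where the walk halted on an unbridgeable
    gap, ``ambiguous_at`` lists positions recorded with >1 candidate.
    """

    candidates: dict[int, frozenset] = field(default_factory=dict)
    matched: dict[int, float] = field(default_factory=dict)
    gap_at: int | None = None
    ambiguous_at: list[int] = field(default_factory=list)


@dataclass
class ReadResult:
    """Outcome of a read: the sequence and the evidence behind it.

    ``status`` is ``"unique"`` (every position carries left/right/both
    evidence and a single label), ``"ambiguous"`` (candidate sets are
    reported per unresolved position) or ``"failed"`` (``reason`` says
    why: missing anchor, inter-walk conflict, precursor inconsistency).
    """

    status: str
    sequence: str | None = None
    evidence: dict[int, str] = field(default_factory=dict)
    candidates: dict[int, tuple] = field(default_factory=dict)
    matched_peaks: dict[int, float] = field(default_factory=dict)
    unexplained_peaks: list[float] = field(default_factory=list)
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "sequence": self.sequence,
            "evidence": {str(k): v for k, v in sorted(self.evidence.items())},
            "candidates": {str(k): list(v) for k, v in sorted(self.candidates.items())},
            "matched_peaks": {str(k): v for k, v in sorted(self.matched_peaks.items())},
            "unexplained_peaks": list(self.unexplained_peaks),
            "reason": self.reason,
        }


# ---------------------------------------------------------------------------


def validate_alphabet(alphabet: Alphabet, cfg: ReaderConfig) -> None:
    """Reject alphabets whose mass spacing cannot support the tolerance."""
    ref_mz = max(b.unit_mass for b in alphabet.blocks)
    tol = cfg.tol_at(ref_mz)
    gap = alphabet.min_mass_gap()
    if gap <= 2 * tol:
        raise ConfigError(
            f"minimum alphabet mass gap {gap:.4g} Da must exceed twice the "
            f"tolerance ({2 * tol:.4g} Da)"
        )


def filter_peaks(pl: PeakList, cfg: ReaderConfig) -> PeakList:
    """Drop peaks at or below the signal-to-noise threshold.

    Noise floor: ``pl.noise_level`` if present, else the median peak
    intensity (recorded on the result, which makes filtering idempotent).
    """
    if len(pl) == 0:
        return pl
    noise = pl.noise_level
    if noise is None:
        noise = float(np.median(pl.intensity))
    if noise > 0:
        keep = pl.intensity / noise > cfg.snr_min
    else:
        keep = np.ones(len(pl), dtype=bool)
    return PeakList(
        pl.mz[keep],
        pl.intensity[keep],
        precursor_mz=pl.precursor_mz,
        noise_level=noise,
        title=pl.title,
    )


def _nearest(mz: np.ndarray, target: float, tol: float) -> float | None:
    """Nearest peak m/z within ±tol, or None.  Warns on near-ties."""
    if mz.size == 0:
        return None
    i = int(np.searchsorted(mz, target))
    best, n_in = None, 0
    for j in (i - 1, i):
        if 0 <= j < mz.size and abs(mz[j] - target) <= tol:
            n_in += 1
            if best is None or abs(mz[j] - target) < abs(best - target):
                best = float(mz[j])
    if n_in > 1:
        log.warning(
            "two peaks within %.4g Da of theoretical mass %.4f; taking the nearer",
            tol, target,
        )
    return best


def _first_rung_base(side: str, model: MassModel) -> float:
    if side == LEFT:
        return model.alpha_mass + model.delta_left + model.adduct_mass
    return model.omega_mass + model.delta_right + model.adduct_mass


def anchor_search(
    pl: PeakList,
    alphabet: Alphabet,
    model: MassModel,
    cfg: ReaderConfig,
) -> tuple[list[Anchor], list[Anchor]]:
    """Find first-rung fragment peaks of both series.

    A left anchor is a peak within tolerance of
    ``alpha + u(b) + delta_left + adduct`` for some block ``b`` (the
    smallest start-containing fragment); right anchors are symmetric with
    the ω-end.  An anchor keeps *all* labels whose theoretical mass it
    matches — ambiguity propagates instead of being silently resolved.

    Raises :class:`AnchorMissingError` if ``cfg.require_both_anchors`` and
    one side has no direct anchor.  (The full reader additionally tries a
    two-unit bridged start before giving up on a side.)
    """
    left, right = _direct_anchors(pl, alphabet, model, cfg)
    if cfg.require_both_anchors:
        for side, anchors in ((LEFT, left), (RIGHT, right)):
            if not anchors:
                raise AnchorMissingError(side)
    return left, right


def _direct_anchors(pl, alphabet, model, cfg):
    out = []
    for side in (LEFT, RIGHT):
        base = _first_rung_base(side, model)
        hits: dict[float, list[str]] = {}
        for b in alphabet.blocks:
            target = base + b.unit_mass
            peak = _nearest(pl.mz, target, cfg.tol_at(target))
            if peak is not None:
                hits.setdefault(peak, []).append(b.label)
        anchors = [Anchor(mz, tuple(sorted(labs))) for mz, labs in hits.items()]
        anchors.sort(key=lambda a: a.mz)
        out.append(anchors)
    return out[0], out[1]


def _pos_of_rung(side: str, rung: int, length: int) -> int:
    return rung if side == LEFT else length - rung + 1


def ladder_walk(
    pl: PeakList,
    start_mass: float,
    direction: str,
    length: int,
    alphabet: Alphabet,
    model: MassModel,
    cfg: ReaderConfig,
    *,
    first_rung: int = 1,
) -> WalkResult:
    """Walk one fragment ladder from a matched anchor peak.

    ``start_mass`` is the measured m/z of rung ``first_rung`` (whose label
    candidates are the anchor's business, not the walk's).  Each step
    re-anchors on the measured peak, so mass jitter does not accumulate.
    A missing rung is bridged with a two-unit jump when
    ``cfg.max_missing_per_position`` allows; an unbridgeable gap or an
    unresolvable multi-peak ambiguity halts the walk — partial results are
    legitimate and the complementary walk covers the rest.
    """
    if direction not in (LEFT, RIGHT):
        raise ConfigError(f"direction must be 'left' or 'right', got {direction!r}")
    res = WalkResult()
    m = start_mass
    rung = first_rung
    blocks = alphabet.blocks
    while rung < length:
        nxt = rung + 1
        pos = _pos_of_rung(direction, nxt, length)
        hits = []
        for b in blocks:
            target = m + b.unit_mass
            peak = _nearest(pl.mz, target, cfg.tol_at(target))
            if peak is not None:
                hits.append((b.label, peak))
        if len(hits) == 1:
            lab, peak = hits[0]
            res.candidates[pos] = frozenset([lab])
            res.matched[pos] = peak
            m, rung = peak, nxt
            continue
        if len(hits) > 1:
            res.candidates[pos] = frozenset(lab for lab, _ in hits)
            res.ambiguous_at.append(pos)
            peaks = {p for _, p in hits}
            if len(peaks) == 1:
                m, rung = peaks.pop(), nxt
                continue
            break
        # no single-unit hit: try to bridge one missing rung
        if cfg.max_missing_per_position >= 1 and nxt < length:
            bridged = _bridge(pl, m, alphabet, cfg)
            if bridged is not None:
                peak, first_labels, second_labels = bridged
                pos2 = _pos_of_rung(direction, nxt + 1, length)
                res.candidates[pos] = first_labels
                res.candidates[pos2] = second_labels
                res.matched[pos2] = peak
                if len(first_labels) > 1:
                    res.ambiguous_at.append(pos)
                if len(second_labels) > 1:
                    res.ambiguous_at.append(pos2)
                m, rung = peak, nxt + 1
                continue
        res.gap_at = pos
        break
    return res


def _bridge(pl, m, alphabet, cfg):
    """Two-unit jump over one missing rung.

    Returns (peak, labels for nearer position, labels for farther
    position) when all pair hits land on a single peak; None otherwise.
    """
    hits = []
    for b1 in alphabet.blocks:
        for b2 in alphabet.blocks:
            target = m + b1.unit_mass + b2.unit_mass
            peak = _nearest(pl.mz, target, cfg.tol_at(target))
            if peak is not None:
                hits.append((b1.label, b2.label, peak))
    if not hits:
        return None
    peaks = {p for _, _, p in hits}
    if len(peaks) > 1:
        # bridging to different peaks: too ambiguous to continue safely
        return None
    peak = peaks.pop()
    first = frozenset(h[0] for h in hits)
    second = frozenset(h[1] for h in hits)
    return peak, first, second


def _side_read(pl, side, anchors, length, alphabet, model, cfg):
    """Anchor one series (directly or bridged) and walk it.

    Returns (candidates, matched, anchored: bool).
    """
    best = None
    for anchor in anchors:
        walk = ladder_walk(pl, anchor.mz, side, length, alphabet, model, cfg)
        pos1 = _pos_of_rung(side, 1, length)
        cands = {pos1: frozenset(anchor.labels)}
        matched = {pos1: anchor.mz}
        cands.update(walk.candidates)
        matched.update(walk.matched)
        if best is None or len(cands) > len(best[0]):
            best = (cands, matched)
    if best is not None:
        return best[0], best[1], True

    # no direct first rung: try a bridged start over the missing anchor
    if cfg.max_missing_per_position >= 1 and length >= 2:
        base = _first_rung_base(side, model)
        bridged = _bridge(pl, base, alphabet, cfg)
        if bridged is not None:
            peak, first_labels, second_labels = bridged
            pos1 = _pos_of_rung(side, 1, length)
            pos2 = _pos_of_rung(side, 2, length)
            cands = {pos1: first_labels, pos2: second_labels}
            matched = {pos2: peak}
            walk = ladder_walk(
                pl, peak, side, length, alphabet, model, cfg, first_rung=2
            )
            cands.update(walk.candidates)
            matched.update(walk.matched)
            return cands, matched, True
    return {}, {}, False


def read_sequence(
    pl: PeakList,
    alphabet: Alphabet,
    model: MassModel,
    length: int,
    cfg: ReaderConfig | None = None,
) -> ReadResult:
    """Reconstruct a sequence of known ``length`` from an MS/MS peak list.

    Runs S/N filtering, anchors and walks both ladder series, and merges
    the two directional reads: positions claimed by both walks must agree
    on the label; positions claimed by one walk are accepted; positions
    claimed by neither leave the read ambiguous.  A unique read is finally
    checked against the precursor mass.
    """
    cfg = cfg or ReaderConfig()
    if length < 1:
        raise ConfigError("sequence length must be >= 1")
    validate_alphabet(alphabet, cfg)
    fpl = filter_peaks(pl, cfg)

    left_anchors, right_anchors = _direct_anchors(fpl, alphabet, model, cfg)

    lc, lm, l_ok = _side_read(fpl, LEFT, left_anchors, length, alphabet, model, cfg)
    rc, rm, r_ok = _side_read(fpl, RIGHT, right_anchors, length, alphabet, model, cfg)

    if cfg.require_both_anchors:
        for side, ok in ((LEFT, l_ok), (RIGHT, r_ok)):
            if not ok:
                return ReadResult(status="failed", reason=f"no {side} anchor found")
    if not (l_ok or r_ok):
        return ReadResult(status="failed", reason="no anchor found on either side")

    merged: dict[int, frozenset] = {}
    evidence: dict[int, str] = {}
    matched: dict[int, float] = {}
    for pos in range(1, length + 1):
        in_l, in_r = pos in lc, pos in rc
        if in_l and in_r:
            inter = lc[pos] & rc[pos]
            if not inter:
                return ReadResult(
                    status="failed",
                    reason=f"left and right walks disagree at position {pos}",
                    candidates={pos: tuple(sorted(lc[pos] | rc[pos]))},
                )
            merged[pos] = inter
            evidence[pos] = "both"
        elif in_l:
            merged[pos] = lc[pos]
            evidence[pos] = LEFT
        elif in_r:
            merged[pos] = rc[pos]
            evidence[pos] = RIGHT
        if pos in lm:
            matched[pos] = lm[pos]
        elif pos in rm:
            matched[pos] = rm[pos]

    uncovered = [p for p in range(1, length + 1) if p not in merged]
    multi = [p for p in merged if len(merged[p]) > 1]

    if uncovered or multi:
        candidates = {p: tuple(sorted(merged[p])) for p in merged}
        # complementary-mass inference for a single uncovered position
        if len(uncovered) == 1 and not multi and fpl.precursor_mz is not None:
            p = uncovered[0]
            known = sum(
                alphabet.mass(next(iter(merged[q]))) for q in merged
            )
            residual = (
                fpl.precursor_mz * model.charge
                - model.alpha_mass - model.omega_mass - model.adduct_mass
                - known
            )
            tol = 2 * cfg.tol_at(fpl.precursor_mz)
            candidates[p] = tuple(
                sorted(
                    b.label for b in alphabet.blocks
                    if abs(b.unit_mass - residual) <= tol
                )
            )
        else:
            for p in uncovered:
                candidates.setdefault(p, ())
        return ReadResult(
            status="ambiguous",
            evidence=evidence,
            candidates=candidates,
            matched_peaks=matched,
            reason=(
                f"unresolved position(s) {sorted(set(uncovered) | set(multi))}"
            ),
        )

    seq = "".join(next(iter(merged[p])) for p in range(1, length + 1))

    if fpl.precursor_mz is not None:
        theo = oligomer_mass(seq, model, alphabet)
        if abs(theo - fpl.precursor_mz) > cfg.tol_at(theo):
            return ReadResult(
                status="failed",
                sequence=seq,
                evidence=evidence,
                reason=(
                    f"precursor m/z {fpl.precursor_mz:.4f} inconsistent with "
                    f"reconstructed sequence ({theo:.4f})"
                ),
            )

    unexplained = _unexplained(fpl, seq, alphabet, model, cfg)
    return ReadResult(
        status="unique",
        sequence=seq,
        evidence=evidence,
        candidates={p: tuple(merged[p]) for p in merged},
        matched_peaks=matched,
        unexplained_peaks=unexplained,
    )


def _unexplained(fpl, seq, alphabet, model, cfg):
    from .massmodel import fragment_ladders

    ladder = fragment_ladders(seq, model, alphabet)
    theo = sorted(ladder.prefix + ladder.suffix + (ladder.precursor,))
    out = []
    for mz in fpl.mz:
        tol = cfg.tol_at(mz)
        i = int(np.searchsorted(theo, mz))
        near = min(
            (abs(theo[j] - mz) for j in (i - 1, i) if 0 <= j < len(theo)),
            default=np.inf,
        )
        if near > tol:
            out.append(float(mz))
    return out
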