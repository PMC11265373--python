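"""Per-assembly screens: telomere completeness, windowed GC/gene density, RIP.

Telomere screen: a contig end is telomeric when at least ``min_copies``
tandem copies of the repeat motif (TTAGGG by default, or its reverse
complement) lie with the run's terminus-side edge inside ``end_window`` bp of
that contig end.  Contigs hit at both ends are complete chromosomes.

RIP screen: sliding-window dinucleotide indices,

    product   = TpA / ApT            (>= 1.1 suggests RIP)
    substrate = (CpA + TpG) / (ApC + GpT)   (<= 0.9 suggests depleted substrate)
    composite = product - substrate  (> 0)

a window is flagged only when all three criteria hold and both denominators
are non-zero; the genome-level affected fraction is the merged flagged span
divided by genome length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Assembly, GeneAnnotation

__all__ = [
    "TelomereConfig",
    "TelomereReport",
    "scan_telomeres",
    "window_stats",
    "RipConfig",
    "RipReport",
    "scan_rip",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------

@dataclass
class TelomereConfig:
    motif: str = "TTAGGG"
    min_copies: int = 3
    end_window: int = 500
    allow_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("telomere motif must be non-empty")
        if self.end_window < self.min_copies * len(self.motif):
            raise ValueError("end_window too small to hold min_copies of the motif")


@dataclass
class TelomereReport:
    genome_id: str
    per_contig: pd.DataFrame  # left_end_hit right_end_hit copies_left copies_right status
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            vc = self.per_contig["status"].value_counts()
            self.counts = {s: int(vc.get(s, 0)) for s in ("complete", "one_end", "none")}


def _tandem_runs(seq: str, motif: str) -> list[tuple[int, int, int]]:
    """(start, end, copies) of maximal tandem runs of ``motif`` in ``seq``."""
    out = []
    for m in re.finditer(f"(?:{re.escape(motif)})+", seq):
        copies = (m.end() - m.start()) // len(motif)
        out.append((m.start(), m.end(), copies))
    return out


def _end_copies(seq: str, motifs: list[str], end_window: int, min_copies: int) -> tuple[int, int]:
    """Best tandem copy count among runs anchored within end_window of each end."""
    left = right = 0
    n = len(seq)
    for motif in motifs:
        for start, end, copies in _tandem_runs(seq, motif):
            if copies < min_copies:
                continue
            if start < end_window:
                left = max(left, copies)
            if end > n - end_window:
                right = max(right, copies)
    return left, right


def scan_telomeres(assembly: Assembly, config: TelomereConfig | None = None) -> TelomereReport:
    config = config or TelomereConfig()
    motifs = [config.motif]
    if config.allow_reverse_complement:
        rc = reverse_complement(config.motif)
        if rc != config.motif:
            motifs.append(rc)
    rows = []
    for contig_id, seq in assembly.contigs.items():
        left, right = _end_copies(seq, motifs, config.end_window, config.min_copies)
        left_hit, right_hit = left >= config.min_copies, right >= config.min_copies
        status = "complete" if (left_hit and right_hit) else ("one_end" if (left_hit or right_hit) else "none")
        rows.append(
            {
                "contig_id": contig_id,
                "left_end_hit": left_hit,
                "right_end_hit": right_hit,
                "copies_left": left,
                "copies_right": right,
                "status": status,
            }
        )
    df = pd.DataFrame(rows).set_index("contig_id")
    return TelomereReport(genome_id=assembly.genome_id, per_contig=df)


# ---------------------------------------------------------------------------
# windowed gene density and GC
# ---------------------------------------------------------------------------

def window_stats(
    assembly: Assembly,
    annotation: GeneAnnotation | None,
    window_size: int = 100_000,
    step: int | None = None,
) -> pd.DataFrame:
    """Tile each contig with windows and report gene counts and GC fraction.

    A gene is counted in every window containing its start coordinate (a
    unique window when step == window_size, the non-overlapping default).
    The final partial window is kept and flagged.  GC fraction ignores N and
    is NaN for all-N windows.
    """
    step = step or window_size
    if step > window_size:
        raise ValueError("step must be <= window_size for a tiling")
    starts_by_contig: dict[str, list[int]] = {}
    if annotation is not None:
        for rec in annotation.records:
            if rec.contig_id not in assembly.contigs:
                raise ValueError(
                    f"annotation contig {rec.contig_id!r} absent from assembly {assembly.genome_id}"
                )
            starts_by_contig.setdefault(rec.contig_id, []).append(rec.start)
    rows = []
    for contig_id, seq in assembly.contigs.items():
        n = len(seq)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
        acgt_cum = np.concatenate([[0], np.cumsum(is_acgt)])
        gstarts = np.sort(np.array(starts_by_contig.get(contig_id, []), dtype=np.int64))
        w0 = 0
        while w0 < n:
            w1 = min(w0 + window_size, n)
            denom = acgt_cum[w1] - acgt_cum[w0]
            gc = (gc_cum[w1] - gc_cum[w0]) / denom if denom > 0 else np.nan
            count = int(np.searchsorted(gstarts, w1, side="left") - np.searchsorted(gstarts, w0, side="left"))
            rows.append(
                {
                    "contig_id": contig_id,
                    "start": w0,
                    "end": w1,
                    "gene_count": count,
                    "gc_fraction": gc,
                    "partial": w1 - w0 < window_size,
                }
            )
            if w1 >= n:
                break
            w0 += step
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RIP indices
# ---------------------------------------------------------------------------

@dataclass
class RipConfig:
    """Sliding-window RIP index settings.

    The 5 kb default window keeps the sampling noise of the index ratios
    small enough that random sequence is essentially never flagged (the
    ratio SDs scale as 1/sqrt(window); at 1 kb the 1.1/0.9 thresholds sit
    inside the null bulk and flag >10% of random sequence).
    """

    window: int = 5000
    step: int = 2500
    product_min: float = 1.1
    substrate_max: float = 0.9
    composite_min: float = 0.0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must span at least one dinucleotide")
        if self.step < 1:
            raise ValueError("step must be positive")


@dataclass
class RipReport:
    genome_id: str
    windows: pd.DataFrame  # contig_id start end product substrate composite defined rip_flag
    affected_fraction: float
    affected_bp: int
    genome_length: int


_DI = {"TA": 0, "AT": 1, "CA": 2, "TG": 3, "AC": 4, "GT": 5}


def _window_dinuc_counts(seq: str, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Window start positions and a (n_windows, 6) matrix of overlapping
    dinucleotide counts (TA, AT, CA, TG, AC, GT) per window."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    idx = code[arr]
    valid = idx != 255
    di = idx[:-1].astype(np.int16) * 4 + idx[1:]
    di[~(valid[:-1] & valid[1:])] = -1
    # dinucleotide codes in the 4x4 table: TA=12, AT=3, CA=4, TG=14, AC=1, GT=11
    wanted = np.array([12, 3, 4, 14, 1, 11])
    cums = np.zeros((len(wanted), len(di) + 1), dtype=np.int64)
    for k, w in enumerate(wanted):
        cums[k, 1:] = np.cumsum(di == w)
    n = len(seq)
    starts = np.arange(0, max(n - 1, 1), step)
    starts = starts[starts < n - 1]
    ends = np.minimum(starts + window, n)
    counts = np.empty((len(starts), 6), dtype=np.int64)
    for k in range(6):
        counts[:, k] = cums[k, ends - 1] - cums[k, starts]
    return np.stack([starts, ends], axis=1), counts


def scan_rip(assembly: Assembly, config: RipConfig | None = None) -> RipReport:
    config = config or RipConfig()
    frames = []
    affected_bp = 0
    for contig_id, seq in assembly.contigs.items():
        spans, counts = _window_dinuc_counts(seq, config.window, config.step)
        ta, at, ca, tg, ac, gt = (counts[:, k].astype(float) for k in range(6))
        with np.errstate(divide="ignore", invalid="ignore"):
            product = np.where(at > 0, ta / at, np.nan)
            denom = ac + gt
            substrate = np.where(denom > 0, (ca + tg) / denom, np.nan)
        composite = product - substrate
        defined = ~np.isnan(product) & ~np.isnan(substrate)
        flag = (
            defined
            & (product >= config.product_min)
            & (substrate <= config.substrate_max)
            & (composite > config.composite_min)
        )
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": contig_id,
                    "start": spans[:, 0],
                    "end": spans[:, 1],
                    "product": product,
                    "substrate": substrate,
                    "composite": composite,
                    "defined": defined,
                    "rip_flag": flag,
                }
            )
        )
        # merged flagged span on this contig
        flagged = spans[flag]
        if len(flagged):
            order = np.argsort(flagged[:, 0])
            cur_s, cur_e = flagged[order[0]]
            for s, e in flagged[order[1:]]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    affected_bp += cur_e - cur_s
                    cur_s, cur_e = s, e
            affected_bp += cur_e - cur_s
    windows = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    total = assembly.total_length
    return RipReport(
        genome_id=assembly.genome_id,
        windows=windows,
        affected_fraction=affected_bp / total if total else 0.0,
        affected_bp=int(affected_bp),
        genome_length=total,
    )
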