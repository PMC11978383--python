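"""Deterministic genome-pair simulator with planted variants.

The generator edits a random target sequence into a query, and the
editing trace *is* the alignment: the emitted block, the three format
files and the truth variant table are exact by construction, which makes
the simulator the test bed for every other module (round trips, stats,
and in particular exact planted-variant recovery by the caller).

Model: target bases are drawn uniformly over ACGT; each position can
independently receive a substitution (to one of the three other bases),
an insertion (geometric length, bases placed after the position in the
query) or a deletion (geometric run of target bases skipped in the
query).  Defaults (100 kb, SNP rate 0.01, insertion/deletion event rates
0.002, geometric length parameter 0.5) give an assembly-vs-assembly pair
at roughly 1% divergence — the regime the toolkit targets.

Planted events are forced >= 2 bp apart (rejection by cooldown) so the
truth comparison needs only VCF left-normalization, never haplotype
realignment; events are also kept off the first and last target base so
every emitted alignment starts and ends with a match column (chains
require ungapped end blocks).  Identical config (including seed) gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Optional

import numpy as np

from alnkit.core import Cigar, PairwiseBlock, Strand, cigar_from_aligned, revcomp
from alnkit.varcall import SV_MIN_LEN_DEFAULT, Variant

_BASES = np.array(list("ACGT"))
_OTHERS = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}

TARGET_NAME = "ref.chr1"
QUERY_NAME = "qry.chr1"


@dataclass(frozen=True)
class SimConfig:
    length: int = 100_000
    snp_rate: float = 0.01
    ins_rate: float = 0.002
    del_rate: float = 0.002
    indel_len_p: float = 0.5  # geometric length parameter; mean run 1/p
    sv_count: int = 0
    sv_len: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        rates = (self.snp_rate, self.ins_rate, self.del_rate)
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise ValueError("rates must be in [0, 1)")
        if sum(rates) >= 1.0:
            raise ValueError("snp+ins+del rate sum must be < 1")
        if not (0.0 < self.indel_len_p <= 1.0):
            raise ValueError("indel_len_p must be in (0, 1]")
        if self.sv_count < 0 or self.sv_len < 1:
            raise ValueError("sv_count >= 0 and sv_len >= 1 required")


@dataclass
class SimResult:
    config: SimConfig
    target_seq: str
    query_seq: str
    block: PairwiseBlock
    truth: list[Variant]

    @property
    def target_name(self) -> str:
        return self.block.target_name

    @property
    def query_name(self) -> str:
        return self.block.query_name


def _plant_sv_positions(rng: np.random.Generator, cfg: SimConfig) -> dict[int, str]:
    """Pick non-overlapping SV sites (alternating INS/DEL), by rejection."""
    if cfg.sv_count == 0:
        return {}
    span = cfg.sv_len + 4
    if cfg.sv_count * span * 2 > cfg.length:
        raise ValueError("sv_count * sv_len too large for genome length")
    sites: list[int] = []
    while len(sites) < cfg.sv_count:
        pos = int(rng.integers(2, cfg.length - cfg.sv_len - 2))
        if all(abs(pos - s) >= span for s in sites):
            sites.append(pos)
    sites.sort()
    return {pos: ("INS" if i % 2 == 0 else "DEL") for i, pos in enumerate(sites)}


def simulate_pair(config: SimConfig) -> SimResult:
    """Generate a target/query pair; the editing trace is the alignment."""
    rng = np.random.default_rng(config.seed)
    L = config.length
    target = "".join(_BASES[rng.integers(0, 4, size=L)])
    draws = rng.random(L)
    sv_sites = _plant_sv_positions(rng, config)

    t_parts: list[str] = []
    q_parts: list[str] = []
    truth: list[Variant] = []
    q_len = 0  # query bases emitted so far
    snp_hi = config.snp_rate
    ins_hi = snp_hi + config.ins_rate
    del_hi = ins_hi + config.del_rate

    def geom_len() -> int:
        return int(rng.geometric(config.indel_len_p))

    i = 0
    no_event_until = 1  # no event on the first target base
    while i < L:
        forced = sv_sites.get(i)
        event = None
        if forced is not None and i >= no_event_until and i < L - 1:
            event = forced
        elif i >= no_event_until and i < L - 1:
            u = draws[i]
            if u < snp_hi:
                event = "SNP"
            elif u < ins_hi:
                event = "INS"
            elif u < del_hi:
                event = "DEL"

        if event == "SNP":
            alt = _OTHERS[target[i]][int(rng.integers(0, 3))]
            t_parts.append(target[i])
            q_parts.append(alt)
            truth.append(
                Variant(
                    chrom=TARGET_NAME, pos=i + 1, ref=target[i], alt=alt,
                    kind="SNP", svlen=0, end=i + 1,
                    query_name=QUERY_NAME, query_pos=q_len + 1,
                )
            )
            q_len += 1
            no_event_until = i + 3
            i += 1
        elif event == "INS":
            k = config.sv_len if forced == "INS" else geom_len()
            inserted = "".join(_BASES[rng.integers(0, 4, size=k)])
            t_parts.append(target[i])
            q_parts.append(target[i])
            q_len += 1
            t_parts.append("-" * k)
            q_parts.append(inserted)
            truth.append(
                Variant(
                    chrom=TARGET_NAME, pos=i + 1, ref=target[i],
                    alt=target[i] + inserted,
                    kind="INS", svlen=k, end=i + 1,
                    query_name=QUERY_NAME, query_pos=q_len + 1,
                    is_sv=k >= SV_MIN_LEN_DEFAULT,
                )
            )
            q_len += k
            no_event_until = i + 3
            i += 1
        elif event == "DEL":
            k = config.sv_len if forced == "DEL" else geom_len()
            k = min(k, L - 1 - i)  # keep the final base a match column
            if k < 1:
                i += 1
                continue
            deleted = target[i:i + k]
            t_parts.append(deleted)
            q_parts.append("-" * k)
            truth.append(
                Variant(
                    chrom=TARGET_NAME, pos=i, ref=target[i - 1] + deleted,
                    alt=target[i - 1],
                    kind="DEL", svlen=-k, end=i + k,
                    query_name=QUERY_NAME, query_pos=q_len,
                    is_sv=k >= SV_MIN_LEN_DEFAULT,
                )
            )
            no_event_until = i + k + 2
            i += k
        else:
            t_parts.append(target[i])
            q_parts.append(target[i])
            q_len += 1
            i += 1

    t_aln = "".join(t_parts)
    q_aln = "".join(q_parts)
    query = q_aln.replace("-", "")
    block = PairwiseBlock(
        target_name=TARGET_NAME,
        target_size=L,
        target_start=0,
        target_end=L,
        query_name=QUERY_NAME,
        query_size=len(query),
        query_strand=Strand("+"),
        query_start=0,
        query_end=len(query),
        cigar=cigar_from_aligned(t_aln, q_aln),
        target_aln=t_aln,
        query_aln=q_aln,
    )
    return SimResult(
        config=config, target_seq=target, query_seq=query,
        block=block, truth=truth,
    )


def flip_query_strand(sim_or_block, query_seq: Optional[str] = None):
    """Re-express a block against the reverse-complemented query genome.

    The alignment itself is unchanged — the same query bases are simply
    addressed from the other strand — so the aligned strings and CIGAR
    stay identical while the strand flag flips and the forward interval
    reflects.  Returns ``(block, flipped_query_seq)`` when a query
    sequence is given, else just the block.
    """
    from dataclasses import replace

    block = sim_or_block.block if isinstance(sim_or_block, SimResult) else sim_or_block
    qsize = block.query_size
    flipped = replace(
        block,
        query_strand=block.query_strand.flipped(),
        query_start=qsize - block.query_end,
        query_end=qsize - block.query_start,
    )
    if query_seq is None and isinstance(sim_or_block, SimResult):
        query_seq = sim_or_block.query_seq
    if query_seq is not None:
        return flipped, revcomp(query_seq)
    return flipped


# ---------------------------------------------------------------------------
# file emission


def write_fasta(path: str, name: str, seq: str, width: int = 60) -> None:
    with open(path, "w", encoding="ascii") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_truth_tsv(truth, stream: IO[str]) -> None:
    stream.write("chrom\tpos\tref\talt\tkind\tsvlen\n")
    for v in truth:
        stream.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.kind}\t{v.svlen}\n")


def emit_formats(sim: SimResult, prefix: str) -> dict[str, str]:
    """Write <prefix>.{t.fa,q.fa,maf,paf,chain,truth.tsv}; return the paths.

    The three alignment files are mutually consistent: converting any of
    them into another reproduces it (up to the documented =/X -> M
    coarsening of Chain).
    """
    from alnkit.convert import block_to_chain, block_to_paf
    from alnkit.io.chain import write_chain
    from alnkit.io.maf import pairwise_to_maf_block, write_maf
    from alnkit.io.paf import write_paf

    paths = {
        "target_fasta": f"{prefix}.t.fa",
        "query_fasta": f"{prefix}.q.fa",
        "maf": f"{prefix}.maf",
        "paf": f"{prefix}.paf",
        "chain": f"{prefix}.chain",
        "truth": f"{prefix}.truth.tsv",
    }
    write_fasta(paths["target_fasta"], sim.target_name, sim.target_seq)
    write_fasta(paths["query_fasta"], sim.query_name, sim.query_seq)
    with open(paths["maf"], "w", encoding="ascii") as fh:
        write_maf([pairwise_to_maf_block(sim.block)], fh)
    with open(paths["paf"], "w", encoding="ascii") as fh:
        write_paf([block_to_paf(sim.block)], fh)
    with open(paths["chain"], "w", encoding="ascii") as fh:
        write_chain([block_to_chain(sim.block, chain_id=1)], fh)
    with open(paths["truth"], "w", encoding="ascii") as fh:
        write_truth_tsv(sim.truth, fh)
    return paths
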