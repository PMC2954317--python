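"""Exon-exon junction references and junction-level read counting.

Transcript variants are quantified by the reads that cross their splice
junctions.  A junction reference holds one 84-nt sequence per (variant,
adjacent exon pair) — 42 nt from the end of the donor exon and 42 nt from
the start of the acceptor exon.  Short reads (50 nt by default) are matched
ungapped against these sequences, allowing a mismatch budget over the full
read, and only uniquely best-matching reads are counted.  Counts are
normalised to RPM (reads per million aligned reads) with no transcript
length adjustment, matching the 3'-biased coverage of the underlying
amplification protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLANK = 42  #: bases taken from each exon side of a junction
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon sequences of one transcript variant (5'->3')."""

    gene_id: str
    variant_id: str
    exons: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.variant_id}: variant has no exons")
        for e in self.exons:
            if not e or any(c not in "ACGTNacgtn" for c in e):
                raise ValueError(f"{self.variant_id}: invalid exon sequence")


def load_gene_models(path) -> list[GeneModel]:
    """Read gene models from a minimal exon TSV.

    Columns: gene, variant, exon_index (1-based order along the transcript),
    sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "variant", "exon_index", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"exon TSV must have columns {sorted(required)}")
    df["exon_index"] = df["exon_index"].astype(int)
    models = []
    for (gene, variant), grp in df.groupby(["gene", "variant"], sort=True):
        grp = grp.sort_values("exon_index")
        models.append(GeneModel(gene, variant, tuple(grp["sequence"])))
    return models


@dataclass
class JunctionReference:
    """Junction table with one row per (variant, adjacent exon pair).

    ``entries`` columns: junction_id, gene_id, variant_id, donor_exon,
    acceptor_exon, sequence (length 84), shared (same sequence occurs for
    another variant of the same gene).  ``skipped`` records junctions
    dropped because an exon flank was shorter than 42 nt.
    """

    entries: pd.DataFrame
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "variant_id", "donor_exon", "acceptor_exon", "reason"]
        )
    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def junction_ids(self) -> pd.Index:
        return pd.Index(self.entries["junction_id"])

    def discriminating_junctions(self) -> pd.DataFrame:
        """Junctions usable for per-variant attribution (shared == False)."""
        return self.entries[~self.entries["shared"]]

    def to_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(row.sequence), id=row.junction_id, description="")
            for row in self.entries.itertuples()
        ]
        seqio_write(records, str(path), "fasta")

    def to_map_tsv(self, path) -> None:
        self.entries.drop(columns="sequence").to_csv(path, sep="\t", index=False)


def build_junction_reference(
    gene_models: Iterable[GeneModel], flank: int = FLANK
) -> JunctionReference:
    """Enumerate exon-exon junctions, taking ``flank`` nt from each exon end.

    Junctions whose donor or acceptor exon is shorter than ``flank`` are
    skipped (and logged) rather than emitted short, so every retained entry
    has the full 2*flank sequence.  Entries whose sequence coincides with
    another variant of the same gene are kept but flagged ``shared``; such
    junctions cannot attribute reads to a single variant.
    """
    rows, skipped = [], []
    for model in gene_models:
        for i in range(len(model.exons) - 1):
            donor, acceptor = model.exons[i].upper(), model.exons[i + 1].upper()
            if len(donor) < flank or len(acceptor) < flank:
                skipped.append(
                    {
                        "gene_id": model.gene_id,
                        "variant_id": model.variant_id,
                        "donor_exon": i + 1,
                        "acceptor_exon": i + 2,
                        "reason": f"flank shorter than {flank} nt",
                    }
                )
                logger.warning(
                    "skipping junction %s:%s exon%d-exon%d (flank < %d nt)",
                    model.gene_id, model.variant_id, i + 1, i + 2, flank,
                )
                continue
            rows.append(
                {
                    "junction_id": f"{model.gene_id}|{model.variant_id}|J{i + 1}",
                    "gene_id": model.gene_id,
                    "variant_id": model.variant_id,
                    "donor_exon": i + 1,
                    "acceptor_exon": i + 2,
                    "sequence": donor[-flank:] + acceptor[:flank],
                }
            )
    entries = pd.DataFrame(
        rows,
        columns=[
            "junction_id", "gene_id", "variant_id",
            "donor_exon", "acceptor_exon", "sequence",
        ],
    )
    if len(entries):
        # shared = identical sequence under a different variant of the same gene
        nvar = entries.groupby(["gene_id", "sequence"])["variant_id"].transform("nunique")
        entries["shared"] = nvar > 1
    else:
        entries["shared"] = pd.Series(dtype=bool)
    if entries["junction_id"].duplicated().any():
        raise ValueError("duplicate junction ids")
    return JunctionReference(entries=entries, skipped=pd.DataFrame(skipped))


@dataclass(frozen=True)
class AlignmentParams:
    """Matching parameters: mismatch budget over the full read, uniqueness."""

    max_mismatches: int = 4
    read_length: int = 50
    require_unique: bool = True
    both_strands: bool = True
    min_overhang: int = 1  #: bases required on each side of the splice point

    def __post_init__(self) -> None:
        if not 0 <= self.max_mismatches < self.read_length:
            raise ValueError("need 0 <= max_mismatches < read_length")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")


@dataclass
class JunctionCountTable:
    """Junction x sample counts with per-sample library sizes and RPM."""

    counts: pd.DataFrame
    library_size: pd.Series
    stats: pd.DataFrame  #: per-sample assigned/ambiguous/unassigned/skipped

    @property
    def rpm(self) -> pd.DataFrame:
        return rpm_normalize(self.counts, self.library_size)


def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).upper().encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), -1)


def match_reads(
    reads: Mapping[str, Sequence[str]] | Sequence[str],
    reference: JunctionReference,
    params: AlignmentParams = AlignmentParams(),
    library_size: Mapping[str, int] | None = None,
) -> JunctionCountTable:
    """Assign reads to junctions by best ungapped placement.

    A read is assigned to a junction when some ungapped offset placement that
    spans the splice point (``min_overhang`` bases on each side) has Hamming
    distance <= ``max_mismatches``; both orientations are tried unless
    ``both_strands`` is off.  If the best distance is achieved on two or more
    junctions the read is discarded as ambiguous (``require_unique``).

    ``reads`` is either {sample: sequences} or a plain sequence (treated as a
    single sample "sample").  ``library_size`` (total uniquely aligned reads
    of each sample) defaults to the number of input reads per sample.
    """
    if not isinstance(reads, Mapping):
        reads = {"sample": list(reads)}
    jids = list(reference.entries["junction_id"])
    ref_len = 2 * FLANK
    L = params.read_length
    ref_enc = _encode(list(reference.entries["sequence"])) if jids else None

    # offsets whose window [o, o+L) covers the splice point with the overhang
    boundary = FLANK
    offsets = [
        o
        for o in range(ref_len - L + 1)
        if o <= boundary - params.min_overhang and o + L >= boundary + params.min_overhang
    ] if jids and L <= ref_len else []

    counts = pd.DataFrame(0, index=pd.Index(jids, name="junction_id"), columns=list(reads))
    stats_rows = {}
    for sample, seqs in reads.items():
        seqs = list(seqs)
        good = [s for s in seqs if len(s) == L]
        n_skipped = len(seqs) - len(good)
        if n_skipped:
            logger.warning("%s: skipped %d reads with length != %d", sample, n_skipped, L)
        assigned = ambiguous = unassigned = 0
        if good and offsets:
            dist = np.full((len(good), len(jids)), L + 1, dtype=np.int32)
            variants = [_encode(good)]
            if params.both_strands:
                variants.append(_encode([reverse_complement(s) for s in good]))
            for enc in variants:
                for o in offsets:
                    window = ref_enc[:, o : o + L]
                    d = (enc[:, None, :] != window[None, :, :]).sum(axis=2)
                    np.minimum(dist, d, out=dist)
            best = dist.min(axis=1)
            for r in range(len(good)):
                if best[r] > params.max_mismatches:
                    unassigned += 1
                    continue
                winners = np.flatnonzero(dist[r] == best[r])
                if len(winners) > 1 and params.require_unique:
                    ambiguous += 1
                    continue
                counts.iloc[winners[0], counts.columns.get_loc(sample)] += 1
                assigned += 1
        else:
            unassigned = len(good)
        stats_rows[sample] = {
            "assigned": assigned,
            "ambiguous": ambiguous,
            "unassigned": unassigned,
            "skipped": n_skipped,
            "total": len(seqs),
        }
    if library_size is None:
        lib = pd.Series({s: len(list(v)) for s, v in reads.items()}, dtype=int)
    else:
        lib = pd.Series(dict(library_size), dtype=int)
    lib = lib.reindex(counts.columns)
    return JunctionCountTable(counts=counts, library_size=lib, stats=pd.DataFrame(stats_rows).T)


def rpm_normalize(counts, library_size):
    """Reads-per-million: count / library_size * 1e6, no length adjustment.

    ``counts`` may be a scalar, array, Series or junction x sample DataFrame;
    ``library_size`` a scalar or per-sample Series aligned to the columns.
    """
    if np.isscalar(library_size):
        if library_size <= 0:
            raise ValueError("library_size must be > 0")
        return np.asarray(counts) / library_size * 1e6 if not np.isscalar(counts) else counts / library_size * 1e6
    lib = pd.Series(library_size)
    if (lib <= 0).any():
        raise ValueError("library_size must be > 0 for every sample")
    if isinstance(counts, pd.DataFrame):
        return counts.div(lib, axis=1) * 1e6
    return pd.Series(counts) / lib * 1e6


def fold_change(rpm_a, rpm_b, floor: float = 0.1):
    """Ratio a/b with both values floored at the detection pseudo-RPM.

    The floor (default 0.1 RPM, the detection limit used throughout) keeps
    ratios finite for undetected features; away from the floor
    fold_change(a, b) * fold_change(b, a) == 1.
    """
    a = np.maximum(np.asarray(rpm_a, dtype=float), floor)
    b = np.maximum(np.asarray(rpm_b, dtype=float), floor)
    out = a / b
    return float(out) if out.ndim == 0 else out
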