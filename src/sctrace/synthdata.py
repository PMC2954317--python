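"""Synthetic inputs for the ICM-to-ESC pipeline, with recorded ground truth.

The generators emulate the study design end-to-end so every downstream
stage is testable without external data:

* a staged single-cell count matrix — stages E3.5 ICM, E4.5 epiblast, day-3
  and day-5 outgrowth cells (Oct4+ and Oct4-) and ESCs, with planted
  stage-specific expression programs, negative-binomial counts and a
  logistic detection dropout that mimics the detection limit of
  low-expressed transcripts;
* junction reads — 50-nt reads drawn across 84-nt exon-exon junction
  sequences in proportion to variant abundance, with substitution errors;
* single-cell qPCR Ct panels — pluripotent cells carry marker Ct in the
  high-expression band (19-28 cycles), lost markers sit at the 40-cycle
  ceiling;
* replicate miRNA profiles and three target-prediction tables with a
  planted class enrichment.

Every generator is deterministic under its seed, and all planted truth is
recoverable by direct counting on the emitted tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import junction_quant as jq

DEFAULT_STAGES = (
    ("ICM", 9),
    ("Epiblast", 3),
    ("Day3_Oct4pos", 2),
    ("Day5_Oct4pos", 3),
    ("Day5_Oct4neg", 2),
    ("ESC", 12),
)
PLURIPOTENT_STAGES = ("ICM", "Epiblast", "Day3_Oct4pos", "Day5_Oct4pos", "ESC")
HIGH_CT_BAND = (19.0, 28.0)
CT_CEILING = 40.0


@dataclass
class PopulationConfig:
    """Design of the synthetic staged cell population.

    ``program`` holds per-gene per-stage mean expression on the RPM scale;
    internally each stage column is treated as a composition and rescaled to
    1e6 RPM, so realised RPM tracks the programmed values while the per-cell
    library size equals the column sum of generated counts.  ``dispersion``
    is the negative-binomial shape r (variance = mu + mu^2/r; r = inf gives
    the Poisson limit), scalar or per-gene.  ``dropout_midpoint`` is the
    mean RPM at which a gene's detection probability is 0.5 (<= 0 disables
    dropout); ``dropout_slope`` is the logistic slope in log2-RPM units.
    ``library_size_range`` is the per-cell sequencing depth draw (uniform).
    """

    stages: tuple[tuple[str, int], ...] = DEFAULT_STAGES
    program: pd.DataFrame | None = None
    dispersion: float | pd.Series = 2.0
    dropout_midpoint: float = 0.5
    dropout_slope: float = 1.5
    library_size_range: tuple[int, int] = (600_000, 1_100_000)
    seed: int = 0

    def validate(self) -> None:
        if not self.stages or any(n < 1 for _, n in self.stages):
            raise ValueError("every stage needs at least one cell")
        if self.program is None:
            raise ValueError("population config needs a program table")
        vals = self.program.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("program means must be finite and >= 0")
        disp = np.asarray(self.dispersion, dtype=float)
        if (disp <= 0).any():
            raise ValueError("dispersion must be > 0")
        stage_names = [s for s, _ in self.stages]
        missing = set(stage_names) - set(self.program.columns)
        if missing:
            raise ValueError(f"program table missing stages: {sorted(missing)}")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    stage_of_cell: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    planted_de_genes: dict = field(default_factory=dict)  #: gene -> true ESC/ICM fold
    anticorrelated_genes: tuple = ()  #: planted r < 0 vs pluripotency (day-5 mix)
    marker_genes: tuple = ()
    program_rpm: pd.DataFrame | None = None  #: normalised per-stage mean RPM
    planted_variant_switches: tuple = ()  #: (gene, variant, direction)
    planted_mirna_targets: dict = field(default_factory=dict)
    mirna_class_genes: tuple = ()
    planted_mirna_folds: dict = field(default_factory=dict)


@dataclass
class CountMatrix:
    """Integer counts (genes x cells) with library sizes and stage labels."""

    counts: pd.DataFrame
    library_size: pd.Series
    stage: pd.Series

    @property
    def rpm(self) -> pd.DataFrame:
        lib = self.library_size.mask(self.library_size == 0, 1)
        return self.counts.div(lib, axis=1) * 1e6

    def cells_of(self, *stages: str) -> list[str]:
        return list(self.stage.index[self.stage.isin(stages)])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    def to_mtx(self, prefix) -> None:
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(f"{prefix}.mtx", csr_matrix(self.counts.to_numpy()))
        pd.Series(self.counts.index).to_csv(f"{prefix}.rows.tsv", sep="\t", index=False, header=False)
        pd.Series(self.counts.columns).to_csv(f"{prefix}.cols.tsv", sep="\t", index=False, header=False)


def default_program(
    n_genes: int = 2000,
    n_program_genes: int = 40,
    program_fold: float = 8.0,
    n_anticorrelated: int = 30,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Build the default per-stage expression program.

    A lognormal baseline spans the low/mid/high RPM strata; each stage gets
    ``n_program_genes`` marker genes raised ``program_fold``-fold, giving
    clear stage structure (and >= 8-fold planted ESC/ICM differences).  A
    further ``n_anticorrelated`` early-differentiation genes are high only
    in day-5 Oct4- cells, anti-correlated with pluripotency in the day-5
    mix.  Oct4/Sox2/Nanog are added explicitly: high in every pluripotent
    stage, silenced in Day5_Oct4neg.
    """
    rng = np.random.default_rng(seed)
    stage_names = [s for s, _ in DEFAULT_STAGES]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    base = rng.lognormal(mean=np.log(30.0), sigma=1.6, size=n_genes)
    program = pd.DataFrame(
        np.tile(base[:, None], (1, len(stage_names))), index=genes, columns=stage_names
    )

    cursor = 0
    planted: dict[str, float] = {}
    stage_modules: dict[str, list[str]] = {}
    for stage in stage_names:
        module = genes[cursor : cursor + n_program_genes]
        stage_modules[stage] = module
        cursor += n_program_genes
        program.loc[module, stage] *= program_fold
    for g in stage_modules["ESC"]:
        planted[g] = program_fold  # up in ESC vs ICM
    for g in stage_modules["ICM"]:
        planted[g] = 1.0 / program_fold

    anti = genes[cursor : cursor + n_anticorrelated]
    cursor += n_anticorrelated
    program.loc[anti, :] *= 0.05
    program.loc[anti, "Day5_Oct4neg"] = base[
        [genes.index(g) for g in anti]
    ] * program_fold

    markers = ("Oct4", "Sox2", "Nanog")
    marker_rows = pd.DataFrame(
        {s: [400.0 if s != "Day5_Oct4neg" else 2.0] * 3 for s in stage_names},
        index=list(markers),
    )
    program = pd.concat([marker_rows, program])
    truth = SyntheticTruth(
        planted_de_genes=planted,
        anticorrelated_genes=tuple(anti),
        marker_genes=markers,
    )
    return program, truth


def default_config(seed: int = 0, **program_kwargs) -> tuple[PopulationConfig, SyntheticTruth]:
    program, truth = default_program(seed=seed, **program_kwargs)
    return PopulationConfig(program=program, seed=seed), truth


def generate_counts(
    config: PopulationConfig, truth: SyntheticTruth | None = None
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the staged count matrix under the configured noise model.

    Per cell: a target depth L ~ U(library_size_range); per gene, counts are
    negative binomial with mean (normalised program RPM) / 1e6 * L and shape
    ``dispersion``, then zeroed with probability 1 - p_detect where p_detect
    is logistic in log2 mean RPM around ``dropout_midpoint``.  The recorded
    library size is the realised column sum, so RPM derived from the matrix
    is internally consistent.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = truth or SyntheticTruth()
    stage_names = [s for s, _ in config.stages]
    prog = config.program[stage_names].astype(float)
    totals = prog.sum(axis=0)
    if (totals <= 0).all():
        norm = prog * 0.0
    else:
        norm = prog.div(totals.mask(totals == 0, 1.0), axis=1) * 1e6

    disp = np.asarray(config.dispersion, dtype=float)
    if disp.ndim == 0:
        disp = np.full(len(prog), float(disp))

    cells, stages, cols = [], [], []
    for stage, n_cells in config.stages:
        mu_rpm = norm[stage].to_numpy()
        if config.dropout_midpoint > 0:
            with np.errstate(divide="ignore"):
                z = config.dropout_slope * (
                    np.log2(np.maximum(mu_rpm, 1e-12))
                    - np.log2(config.dropout_midpoint)
                )
            p_detect = 1.0 / (1.0 + np.exp(-z))
            p_detect[mu_rpm == 0] = 0.0
        else:
            p_detect = (mu_rpm > 0).astype(float)
        for i in range(n_cells):
            cell = f"{stage}_{i + 1}"
            L = int(rng.integers(config.library_size_range[0], config.library_size_range[1] + 1))
            mu = mu_rpm / 1e6 * L
            counts = np.zeros(len(mu), dtype=np.int64)
            pos = mu > 0
            finite = np.isfinite(disp)
            nb = pos & finite
            poi = pos & ~finite
            if nb.any():
                r = disp[nb]
                counts[nb] = rng.negative_binomial(r, r / (r + mu[nb]))
            if poi.any():
                counts[poi] = rng.poisson(mu[poi])
            detected = rng.random(len(mu)) < p_detect
            counts[~detected] = 0
            cells.append(cell)
            stages.append(stage)
            cols.append(counts)
    counts = pd.DataFrame(
        np.column_stack(cols) if cols else np.zeros((len(prog), 0)),
        index=prog.index,
        columns=cells,
        dtype=np.int64,
    )
    library_size = counts.sum(axis=0)
    stage_series = pd.Series(stages, index=cells, name="stage")
    planted = truth.planted_de_genes
    if planted and {"ESC", "ICM"}.issubset(norm.columns):
        # true folds on the realised (composition-normalised) RPM scale
        planted = {
            g: float(max(norm.at[g, "ESC"], 0.1) / max(norm.at[g, "ICM"], 0.1))
            for g in planted
        }
    truth = replace(truth, stage_of_cell=stage_series, program_rpm=norm, planted_de_genes=planted)
    return CountMatrix(counts=counts, library_size=library_size, stage=stage_series), truth


# ---------------------------------------------------------------------------
# junction reads


def generate_junction_reads(
    gene_models: Sequence[jq.GeneModel],
    variant_abundances: pd.DataFrame,
    read_length: int = 50,
    mismatch_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], jq.JunctionReference, pd.DataFrame]:
    """Draw junction-spanning reads per sample with known per-junction truth.

    ``variant_abundances`` is variants x samples of integer read counts *per
    junction of that variant*, so a two-variant gene planted at 88:35 yields
    truth junction counts in exactly that ratio.  Each read takes a uniform
    offset among placements spanning the splice point, then substitution
    errors at ``mismatch_rate`` per base.  Junctions with short flanks were
    already skipped (with a warning) by the reference builder.
    """
    if not 0 <= mismatch_rate < 1:
        raise ValueError("mismatch_rate must be in [0, 1)")
    reference = jq.build_junction_reference(gene_models)
    if read_length > 2 * jq.FLANK:
        raise ValueError("read_length exceeds the 84-nt junction length")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    offsets = [
        o
        for o in range(2 * jq.FLANK - read_length + 1)
        if o <= jq.FLANK - 1 and o + read_length >= jq.FLANK + 1
    ]
    reads: dict[str, list[str]] = {s: [] for s in variant_abundances.columns}
    truth = pd.DataFrame(
        0,
        index=pd.Index(reference.entries["junction_id"], name="junction_id"),
        columns=variant_abundances.columns,
    )
    for sample in variant_abundances.columns:
        for row in reference.entries.itertuples():
            if row.variant_id not in variant_abundances.index:
                continue
            n_reads = int(variant_abundances.at[row.variant_id, sample])
            if n_reads < 0:
                raise ValueError("abundances must be >= 0")
            truth.at[row.junction_id, sample] += n_reads
            seq = np.frombuffer(row.sequence.encode(), dtype=np.uint8)
            for _ in range(n_reads):
                o = offsets[rng.integers(len(offsets))]
                read = seq[o : o + read_length].copy()
                if mismatch_rate > 0:
                    hit = rng.random(read_length) < mismatch_rate
                    for pos in np.flatnonzero(hit):
                        choices = bases[bases != read[pos]]
                        read[pos] = choices[rng.integers(len(choices))]
                reads[sample].append(read.tobytes().decode())
    return reads, reference, truth


def write_reads_fasta(reads: Mapping[str, Sequence[str]], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=f"{sample}:read{i + 1}", description="")
        for sample, seqs in reads.items()
        for i, seq in enumerate(seqs)
    ]
    seqio_write(records, str(path), "fasta")


def random_gene_models(
    n_genes: int = 3,
    n_exons: int = 3,
    exon_length: int = 60,
    seed: int = 0,
) -> list[jq.GeneModel]:
    """Random multi-exon gene models; each gene gets a full variant plus a
    cassette-exon-skipping variant, mirroring the two-isoform worked case."""
    rng = np.random.default_rng(seed)
    models = []
    for g in range(n_genes):
        exons = tuple(
            "".join(rng.choice(list("ACGT"), size=exon_length)) for _ in range(n_exons)
        )
        gene = f"gene{g + 1}"
        models.append(jq.GeneModel(gene, f"{gene}.v1", exons))
        if n_exons >= 3:
            models.append(jq.GeneModel(gene, f"{gene}.v2", exons[:1] + exons[2:]))
    return models


# ---------------------------------------------------------------------------
# qPCR Ct matrices


def generate_ct_matrix(
    stage_design: Mapping[str, tuple[int, Mapping[str, object]]],
    seed: int = 0,
    noise_sd: float = 0.5,
    high_band: tuple[float, float] = HIGH_CT_BAND,
) -> "object":
    """Simulate a single-cell Ct panel from a per-stage marker design.

    ``stage_design`` maps stage -> (n_cells, {gene: spec}) where spec is
    ``"high"`` (stage-level centre drawn in the 19-28 band, per-cell Gaussian
    noise clipped to the band), ``"lost"`` (Ct = 40 exactly), or a numeric
    mean Ct (noise applied, clipped to [0, 40)).  Zero noise makes all cells
    of a stage identical.
    """
    from .qpcr_panel import CtMatrix

    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for _, (_, spec) in stage_design.items():
        for g in spec:
            if g not in genes:
                genes.append(g)
    cols, cells, stages = [], [], []
    for stage, (n_cells, spec) in stage_design.items():
        if n_cells < 1:
            raise ValueError(f"stage {stage!r} needs at least one cell")
        centres = {}
        for g, s in spec.items():
            if s == "high":
                centres[g] = rng.uniform(*high_band)
            elif s == "lost":
                centres[g] = CT_CEILING
            else:
                centres[g] = float(s)
        for i in range(n_cells):
            cells.append(f"{stage}_{i + 1}")
            stages.append(stage)
            col = []
            for g in genes:
                if g not in spec:
                    col.append(CT_CEILING)
                    continue
                s, c = spec[g], centres[g]
                if s == "lost":
                    col.append(CT_CEILING)
                elif s == "high":
                    col.append(float(np.clip(c + rng.normal(0, noise_sd) if noise_sd else c, *high_band)))
                else:
                    col.append(float(np.clip(c + rng.normal(0, noise_sd) if noise_sd else c, 0, CT_CEILING - 1e-9)))
            cols.append(col)
    ct = pd.DataFrame(np.array(cols).T, index=genes, columns=cells)
    return CtMatrix(ct=ct, stage=pd.Series(stages, index=cells, name="stage"))


def default_ct_design() -> dict:
    """Marker design mirroring the outgrowth series: all 22 ICM cells triple
    positive; 7 of 18 Oct4-high day-3 cells lose Nanog and/or Sox2; 11 of 13
    Oct4-high day-5 cells keep all three; all 23 ESCs triple positive."""
    markers = ("Oct4", "Sox2", "Nanog")
    high = {m: "high" for m in markers}

    def losing(gene):
        d = dict(high)
        d[gene] = "lost"
        return d

    design: dict[str, tuple[int, dict]] = {}
    design["ICM"] = (22, high)
    # day 3: 18 Oct4-high cells, 7 losing Nanog and/or Sox2
    for i in range(11):
        design[f"Day3_p{i}"] = (1, high)
    for i in range(4):
        design[f"Day3_lN{i}"] = (1, losing("Nanog"))
    for i in range(3):
        design[f"Day3_lS{i}"] = (1, losing("Sox2"))
    # day 5: 13 Oct4-high cells, 2 losing
    for i in range(11):
        design[f"Day5_p{i}"] = (1, high)
    for i in range(2):
        design[f"Day5_lN{i}"] = (1, losing("Nanog"))
    design["ESC"] = (23, high)
    return design


# ---------------------------------------------------------------------------
# miRNA fixture


def _solve_in_class_rate(
    fold: float,
    n_mirnas: int,
    targets_per_mirna: int,
    class_size: int,
    n_genes: int,
    agreement: float,
) -> float:
    """Per-miRNA in-class target fraction realising a pooled enrichment fold.

    Targets are pooled as a set union across the planted miRNAs, which
    saturates the (small) class faster than the rest of the universe; a
    naive per-miRNA plant therefore under-delivers at the pooled level.
    Solve E[pooled fold](q) = fold for q using the expected union coverage
    of class and non-class genes (consensus draws per miRNA approximated as
    agreement * targets_per_mirna; the agreement thinning is uniform so it
    affects only the effective number of draws)."""
    from scipy.optimize import brentq

    K, Nout, m = class_size, n_genes - class_size, n_mirnas
    t_eff = max(agreement, 1e-9) * targets_per_mirna
    class_frac = K / n_genes

    def pooled(qq: float) -> float:
        k = K * (1.0 - (1.0 - qq * t_eff / K) ** m)
        out = Nout * (1.0 - (1.0 - (1.0 - qq) * t_eff / Nout) ** m)
        n = k + out
        if n == 0:
            return 1.0
        return (k / n) / class_frac

    q_hi = min(1.0, K / targets_per_mirna)
    f_lo, f_hi = pooled(0.0), pooled(q_hi)
    if not f_lo <= fold <= f_hi:
        raise ValueError(
            f"planted fold {fold} infeasible at these table sizes: "
            f"achievable range is [{f_lo:.3f}, {f_hi:.3f}] "
            f"(universe {n_genes}, class {class_size}, "
            f"{m} miRNAs x {targets_per_mirna} targets)"
        )
    return float(brentq(lambda qq: pooled(qq) - fold, 0.0, q_hi, xtol=1e-12))


def generate_mirna_fixture(
    n_mirnas: int = 60,
    n_genes: int = 10_000,
    planted_enrichment_fold: float = 2.0,
    n_replicates: int = 3,
    seed: int = 0,
    n_planted_mirnas: int = 10,
    class_size: int = 500,
    targets_per_mirna: int = 300,
    agreement: float = 0.8,
    planted_folds: Mapping[str, float] | None = None,
    replicate_noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """miRNA replicate profiles plus three target-prediction tables.

    Targets of the ``n_planted_mirnas`` planted miRNAs fall in a designated
    gene class at ``planted_enrichment_fold`` times the class's universe
    share; the remaining miRNAs target uniformly.  Each consensus (miRNA,
    gene) pair is written to >= 2 of the three algorithm tables with
    probability ``agreement`` (else to exactly one, so agreement 0 gives an
    empty consensus).  ``planted_folds`` plants ICM->ESC expression ratios
    (ESC/ICM) recovered by :func:`sctrace.enrichment.mirna_de`;
    ``replicate_noise_sd`` is lognormal (log2) replicate noise.

    Returns (profile, long target table with column ``algorithm``, truth).
    """
    rng = np.random.default_rng(seed)
    q = _solve_in_class_rate(
        planted_enrichment_fold,
        n_planted_mirnas,
        targets_per_mirna,
        class_size,
        n_genes,
        agreement,
    )
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    class_genes = genes[:class_size]
    other_genes = genes[class_size:]
    mirnas = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    planted = mirnas[:n_planted_mirnas]
    planted_folds = dict(planted_folds or {})
    named = [m for m in planted_folds if m not in mirnas]
    if n_planted_mirnas + len(named) > n_mirnas:
        raise ValueError("too many named planted_folds for n_mirnas")
    for i, name in enumerate(named):  # give fold-planted miRNAs their names
        mirnas[n_planted_mirnas + i] = name

    algorithms = ("PicTar", "Miranda", "TargetScan")
    rows = []
    truth_targets: dict[str, set] = {}
    for m in mirnas:
        if m in planted:
            n_in = int(round(q * targets_per_mirna))
            tg_in = rng.choice(class_genes, size=min(n_in, class_size), replace=False)
            tg_out = rng.choice(
                other_genes, size=targets_per_mirna - len(tg_in), replace=False
            )
            targets = np.concatenate([tg_in, tg_out])
        else:
            targets = rng.choice(genes, size=targets_per_mirna, replace=False)
        consensus_mask = rng.random(len(targets)) < agreement
        truth_targets[m] = set(targets[consensus_mask])
        for g, is_consensus in zip(targets, consensus_mask):
            if is_consensus:
                k = 2 if rng.random() < 0.7 else 3
                algs = rng.choice(algorithms, size=k, replace=False)
            else:
                algs = [algorithms[rng.integers(3)]]
            for a in algs:
                rows.append({"algorithm": a, "mirna": m, "gene": g})
    target_table = pd.DataFrame(rows, columns=["algorithm", "mirna", "gene"])

    base = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=n_mirnas)
    cols = {}
    for t, scale in (("ICM", np.ones(n_mirnas)), ("ESC", None)):
        if scale is None:
            scale = np.array([planted_folds.get(m, 1.0) for m in mirnas])
        for r in range(n_replicates):
            noise = rng.normal(0, replicate_noise_sd, size=n_mirnas)
            cols[f"{t}_{r + 1}"] = base * scale * np.exp2(noise)
    profile = pd.DataFrame(cols, index=pd.Index(mirnas, name="mirna"))
    truth = SyntheticTruth(
        planted_mirna_targets=truth_targets,
        mirna_class_genes=tuple(class_genes),
        planted_mirna_folds=planted_folds,
    )
    return profile, target_table, truth


def default_mirna_folds(n_differential: int = 51, n_mirnas: int = 330, seed: int = 0) -> dict[str, float]:
    """ESC/ICM fold plan echoing the profiling narrative: the let-7 family
    down 4-12-fold, miR-302c up 5-fold, miR-367 up 33-fold, and enough
    further miRNAs changed >= 4-fold to reach 51 differential of 330."""
    rng = np.random.default_rng(seed)
    folds = {
        "let-7a": 1 / 12,
        "let-7e": 1 / 9,
        "let-7f": 1 / 6,
        "let-7g": 1 / 4.5,
        "miR-302c": 5.0,
        "miR-367": 33.0,
    }
    i = 0
    while len(folds) < n_differential:
        f = float(rng.uniform(4, 16))
        folds[f"miR-d{i:03d}"] = f if i % 2 == 0 else 1 / f
        i += 1
    return folds
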