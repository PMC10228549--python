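"""Synthetic genomes, catalogs and communities with known ground truth.

The generator emulates the structure of a chain-elongation bioreactor MAG
study: a catalog of fermentation-pathway enzymes, genomes whose contigs
embed reverse-translated pathway genes at controlled amino-acid identity on
random strands and frames inside random-nucleotide background, near-clone
genomes at controlled nucleotide divergence for dereplication, and
experiment-structured relative-abundance matrices whose within-experiment
Bray-Curtis dissimilarity is smaller than between-experiment dissimilarity.

Group -> pathway content:

* ``ferment_to_intermediates`` — homolactic and bifid-shunt rosters
  embedded (>=80% of each), lactic-acid-utilization (LAU) and reverse
  beta-oxidation (RBO) nearly absent.
* ``intermediate_ce`` — LAU and RBO embedded; carbohydrate-fermentation
  pathways nearly absent.  These genomes also carry both EtfB variants
  (ecLDH- and ACD-partnered).
* ``carbohydrate_ce`` — RBO embedded, LAU and the heterolactic pathways
  nearly absent.
* ``uninvolved`` — at most one stray enzyme from any pathway.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .records import DEFAULT_PATHWAYS, GROUPS, EnzymeEntry, GenomeRecord, PathwayCatalog

_AA20 = "ARNDCQEGHILKMFPSTWYV"
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

# pathway -> roster size; LAU and RBO sizes reflect the biology (three
# proteins key for lactic-acid conversion; four chain-elongation enzymes),
# the carbohydrate-fermentation rosters are synthetic stand-ins whose only
# relevant property is their size.
DEFAULT_ROSTER_SIZES = {
    "homolactic": 8,
    "phosphoketolase": 9,
    "bifid_shunt": 10,
    "lactic_acid_utilization": 3,
    "reverse_beta_oxidation": 4,
}

_NAMED_ENZYMES = {
    "lactic_acid_utilization": ["ecLDH", "EtfA", "EtfB"],
    "reverse_beta_oxidation": [
        "acetylCoA_C_acetyltransferase",
        "hydroxyacylCoA_dehydrogenase",
        "enoylCoA_hydratase",
        "eb_acylCoA_dehydrogenase",
    ],
}

GROUP_PATHWAYS: dict[str, tuple[str, ...]] = {
    "ferment_to_intermediates": ("homolactic", "bifid_shunt"),
    "intermediate_ce": ("lactic_acid_utilization", "reverse_beta_oxidation"),
    "carbohydrate_ce": ("reverse_beta_oxidation",),
    "uninvolved": (),
}

ETFB_ACD = "EtfB_acd"  # ACD-partnered EtfB companion gene (non-roster)


@dataclass
class SimConfig:
    """Parameters of the synthetic study."""

    seed: int = 0
    n_genomes_per_group: int = 10
    contig_length: int = 50_000  # bp
    n_contigs: int = 4
    gene_identity_levels: tuple[float, ...] = (0.7, 0.8, 0.9, 0.95)
    clone_divergence: float = 0.005  # substitutions per site
    groups: tuple[str, ...] = GROUPS
    abundance_experiments: int = 10
    samples_per_experiment: int = 8
    embed_fraction_min: float = 0.8  # minimum fraction of an assigned roster embedded
    stray_gene_prob: float = 0.5  # chance an unassigned pathway contributes 1 enzyme
    dirichlet_concentration: float = 60.0  # within-experiment sample similarity
    residual_range: tuple[float, float] = (5.0, 35.0)  # unmapped % per sample

    def __post_init__(self) -> None:
        if not all(0 < x <= 1 for x in self.gene_identity_levels):
            raise ValueError("identity levels must lie in (0, 1]")
        if not 0 <= self.clone_divergence <= 0.05:
            raise ValueError("clone_divergence must lie in [0, 0.05]")


@dataclass
class TruthRecord:
    """Ground truth for one synthetic genome."""

    genome_id: str
    true_group: str
    # (pathway, enzyme, contig, strand, frame, start, end, target_identity)
    embedded_genes: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_AA20))[rng.integers(0, 20, length)])


def make_pathway_catalog(
    seed: int,
    roster_sizes: dict[str, int] | None = None,
    length_range: tuple[int, int] = (200, 500),
) -> PathwayCatalog:
    """Generate the default five-pathway catalog of random protein queries.

    LAU always has exactly 3 enzymes (ecLDH, EtfA, EtfB) and RBO exactly 4,
    including acetyl-CoA C-acetyltransferase and the electron-bifurcating
    acyl-CoA dehydrogenase.  An ACD-partnered EtfB companion protein is
    attached as an extra (searched but not a roster member).
    """
    sizes = dict(DEFAULT_ROSTER_SIZES)
    if roster_sizes:
        sizes.update(roster_sizes)
    sizes["lactic_acid_utilization"] = 3
    sizes["reverse_beta_oxidation"] = 4
    rng = np.random.default_rng(seed)
    pathways: dict[str, list[EnzymeEntry]] = {}
    for pw in DEFAULT_PATHWAYS:
        roster = []
        names = _NAMED_ENZYMES.get(pw)
        for i in range(sizes[pw]):
            name = names[i] if names else f"{pw}_enz{i + 1:02d}"
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            roster.append(EnzymeEntry(name, pw, _random_protein(rng, length)))
        pathways[pw] = roster
    catalog = PathwayCatalog(pathways=pathways)
    catalog.extras[ETFB_ACD] = _random_protein(
        rng, int(rng.integers(length_range[0], length_range[1] + 1))
    )
    catalog.mark_unique()
    return catalog


# -- reverse translation and identity control -------------------------------

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()


def mutate_protein(protein: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1-identity)*L) positions with different
    residues, so realized identity equals the target up to rounding."""
    length = len(protein)
    n_mut = int(round((1.0 - target_identity) * length))
    positions = rng.choice(length, size=n_mut, replace=False)
    out = list(protein)
    for p in positions:
        choices = [a for a in _AA20 if a != out[p]]
        out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA (translation table 11), choosing uniformly
    among synonymous codons."""
    parts = []
    for aa in protein:
        codons = _AA_TO_CODONS[aa]
        parts.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(parts)


_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _NT[rng.integers(0, 4, length)].tobytes().decode()


def simulate_genome(
    group: str,
    catalog: PathwayCatalog,
    config: SimConfig,
    genome_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeRecord, TruthRecord]:
    """Build one genome of the given functional group.

    Assigned pathways contribute >= ``embed_fraction_min`` of their roster
    as reverse-translated genes mutated to a sampled target amino-acid
    identity and placed on a random strand/frame; unassigned pathways
    contribute at most one enzyme.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = rng or np.random.default_rng(config.seed)
    gid = genome_id or f"{group}_g{int(rng.integers(0, 10**9)):09d}"

    # choose genes to embed
    chosen: list[tuple[str, str, str, float]] = []  # (pathway, enzyme, protein, identity)
    assigned = GROUP_PATHWAYS[group]
    for pw in catalog.pathway_names:
        roster = catalog.roster(pw)
        if pw in assigned:
            lo = int(np.ceil(config.embed_fraction_min * len(roster)))
            n_embed = int(rng.integers(lo, len(roster) + 1))
            picks = rng.choice(len(roster), size=n_embed, replace=False)
        else:
            if rng.random() < config.stray_gene_prob:
                picks = rng.choice(len(roster), size=1)
            else:
                picks = np.array([], dtype=int)
        for idx in sorted(int(i) for i in picks):
            e = roster[idx]
            ident = float(rng.choice(config.gene_identity_levels))
            chosen.append((pw, e.enzyme, e.sequence, ident))
    # intermediate chain elongators carry the ACD-partnered EtfB companion
    if group == "intermediate_ce" and ETFB_ACD in catalog.extras:
        ident = float(rng.choice(config.gene_identity_levels))
        chosen.append(("companion", ETFB_ACD, catalog.extras[ETFB_ACD], ident))

    # allocate non-overlapping slots on contigs
    contigs: dict[str, list] = {f"{gid}_c{i + 1}": [] for i in range(config.n_contigs)}
    contig_ids = list(contigs)
    cursors = {cid: 0 for cid in contig_ids}
    truth = TruthRecord(genome_id=gid, true_group=group)
    order = rng.permutation(len(chosen))
    for j in order:
        pw, enzyme, protein, ident = chosen[j]
        mutated = mutate_protein(protein, ident, rng)
        gene_nt = reverse_translate(mutated, rng)
        strand = 1 if rng.random() < 0.5 else -1
        if strand == -1:
            gene_nt = revcomp(gene_nt)
        placed = False
        for cid in rng.permutation(contig_ids):
            gap = int(rng.integers(20, 200))
            start0 = cursors[cid] + gap
            end0 = start0 + len(gene_nt)
            if end0 <= config.contig_length:
                contigs[cid].append((start0, gene_nt))
                cursors[cid] = end0
                frame = strand * ((start0 % 3) + 1) if strand == 1 else strand * (
                    ((config.contig_length - end0) % 3) + 1
                )
                truth.embedded_genes.append(
                    (pw, enzyme, cid, strand, int(frame), start0 + 1, end0, ident)
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"contigs of {config.contig_length} bp cannot fit gene "
                f"{enzyme} ({len(gene_nt)} bp) for genome {gid}"
            )

    # fill background and splice genes in
    final: dict[str, str] = {}
    for cid in contig_ids:
        bg = np.frombuffer(_random_dna(rng, config.contig_length).encode(), np.uint8).copy()
        for start0, gene_nt in contigs[cid]:
            bg[start0 : start0 + len(gene_nt)] = np.frombuffer(gene_nt.encode(), np.uint8)
        final[cid] = bg.tobytes().decode()

    genome = GenomeRecord(
        genome_id=gid,
        contigs=final,
        completeness=float(np.round(rng.uniform(75.0, 100.0), 2)),
        contamination=float(np.round(rng.uniform(0.0, 7.5), 2)),
        n50=config.contig_length,
    )
    return genome, truth


def simulate_clone(
    genome: GenomeRecord, divergence: float, seed: int
) -> GenomeRecord:
    """Copy a genome with independent per-site substitutions at the given
    rate (expected ANI = 1 - divergence); quality metrics re-drawn nearby."""
    if not 0 <= divergence <= 0.05:
        raise ValueError("divergence must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    for cid, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), np.uint8).copy()
        hit = rng.random(len(arr)) < divergence
        idx = np.nonzero(hit)[0]
        if idx.size:
            # map A,C,G,T to 0..3, shift by 1..3, map back: always a change
            lut = np.zeros(256, np.uint8)
            lut[_NT] = np.arange(4)
            codes = lut[arr[idx]]
            arr[idx] = _NT[(codes + rng.integers(1, 4, idx.size)) % 4]
        contigs[cid.replace(genome.genome_id, genome.genome_id + "cl", 1)] = (
            arr.tobytes().decode()
        )
    return GenomeRecord(
        genome_id=genome.genome_id + "_clone",
        contigs=contigs,
        completeness=float(np.round(np.clip(genome.completeness + rng.normal(0, 1), 75, 100), 2)),
        contamination=float(np.round(np.clip(genome.contamination + rng.normal(0, 0.5), 0, 7.5), 2)),
        n50=genome.n50,
    )


def simulate_cohort(
    config: SimConfig, catalog: PathwayCatalog | None = None
) -> tuple[PathwayCatalog, list[GenomeRecord], list[TruthRecord]]:
    """Simulate ``n_genomes_per_group`` genomes for every group."""
    catalog = catalog or make_pathway_catalog(config.seed)
    rng = np.random.default_rng(config.seed)
    genomes, truths = [], []
    counter = 0
    for group in config.groups:
        for _ in range(config.n_genomes_per_group):
            counter += 1
            g, t = simulate_genome(
                group, catalog, config, genome_id=f"MAG{counter:04d}_{group}", rng=rng
            )
            genomes.append(g)
            truths.append(t)
    return catalog, genomes, truths


def simulate_derep_cohort(
    n_total: int = 240,
    n_duplicates: int = 23,
    clone_divergence: float = 0.005,
    genome_length: int = 50_000,
    seed: int = 0,
) -> tuple[list[GenomeRecord], list[str]]:
    """Genome set with planted near-clones for dereplication tests.

    ``n_total - n_duplicates`` unrelated random genomes are generated; the
    remaining ``n_duplicates`` are near-clones (at ``clone_divergence``
    substitutions per site, i.e. ANI ~ 1 - divergence) of distinct
    originals, so dereplication at a 99% ANI threshold must yield exactly
    ``n_total - n_duplicates`` representatives.  Returns the genomes and
    the ids of the planted clones.
    """
    if n_duplicates >= n_total:
        raise ValueError("need fewer duplicates than genomes")
    rng = np.random.default_rng(seed)
    originals = []
    for i in range(n_total - n_duplicates):
        gid = f"D{i + 1:04d}"
        originals.append(GenomeRecord(
            genome_id=gid,
            contigs={f"{gid}_c1": _random_dna(rng, genome_length)},
            completeness=float(np.round(rng.uniform(75, 100), 2)),
            contamination=float(np.round(rng.uniform(0, 7.5), 2)),
            n50=genome_length,
        ))
    clone_ids = []
    clones = []
    targets = rng.choice(len(originals), size=n_duplicates, replace=False)
    for j, t in enumerate(sorted(int(x) for x in targets)):
        clone = simulate_clone(originals[t], clone_divergence, seed=int(rng.integers(2**31)))
        clone.genome_id = f"{originals[t].genome_id}_dup"
        clones.append(clone)
        clone_ids.append(clone.genome_id)
    return originals + clones, clone_ids


# -- abundance --------------------------------------------------------------

def simulate_abundance(truths: list[TruthRecord], config: SimConfig):
    """Experiment-structured relative-abundance table.

    Each experiment gets its own Dirichlet(1) base composition; samples
    within an experiment draw from Dirichlet(concentration * base), so
    within-experiment Bray-Curtis dissimilarity is below between-experiment
    dissimilarity in expectation.  Each sample carries an "unmapped"
    residual so MAG fractions sum to exactly 100% with it included.
    """
    from .community import AbundanceTable  # local import to avoid a cycle

    if config.abundance_experiments < 2 or config.samples_per_experiment < 2:
        raise ValueError("need >=2 experiments with >=2 samples each")
    rng = np.random.default_rng(config.seed + 1_000_003)
    genome_ids = [t.genome_id for t in truths]
    n = len(genome_ids)
    if n == 0:
        raise ValueError("no genomes to simulate abundances for")
    columns, experiments, timepoints, data, residuals = [], [], [], [], []
    for e in range(config.abundance_experiments):
        base = rng.dirichlet(np.ones(n))
        alpha = np.maximum(base * config.dirichlet_concentration, 1e-3)
        for s in range(config.samples_per_experiment):
            frac = rng.dirichlet(alpha)
            residual = rng.uniform(*config.residual_range)
            data.append(frac * (100.0 - residual))
            residuals.append(residual)
            columns.append(f"exp{e + 1:02d}_s{s + 1:02d}")
            experiments.append(f"exp{e + 1:02d}")
            timepoints.append(s + 1)
    import pandas as pd

    abundance = pd.DataFrame(
        np.array(data).T, index=genome_ids, columns=columns
    )
    metadata = pd.DataFrame(
        {"sample_id": columns, "experiment": experiments, "timepoint": timepoints}
    )
    return AbundanceTable(
        abundance=abundance,
        residual=pd.Series(residuals, index=columns, name="unmapped"),
        metadata=metadata,
    )
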