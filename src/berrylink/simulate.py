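"""Synthetic phage-host community generator with machine-readable ground truth.

Emulates the structure of a small sulfur-cycling aggregate ("pink berry")
community: a few bacterial host genomes carrying CRISPR arrays whose spacers
are partly copied (with a fixed number of substitutions) from co-occurring
phage genomes, sample-to-sample phage abundance variation, an optional
transposon-mediated HGT scenario (a phage gene copy in a host chromosome,
flanked by short direct repeats and inactivated by a single-base insertion
that creates a premature stop codon), planted allelic variants with elevated
density inside CRISPR-targeted protospacers, and uniform-error short reads.

Everything is deterministic given ``rng_seed``, and every planted feature is
recorded in a :class:`TruthTable` so downstream stages can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqcore import Interval, QualRead, SeqRecord, decode, encode, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ArraySpec:
    n_spacers: int = 10
    spacer_length: int = 34
    repeat_length: int = 36
    repeat_sequence: Optional[str] = None


@dataclass
class HostSpec:
    taxon_label: str
    genome_length: int
    arrays: List[ArraySpec] = field(default_factory=list)
    per_sample_abundance: Optional[List[float]] = None  # default: 1.0 each


@dataclass
class PhageSpec:
    label: str
    genome_length: int
    per_sample_abundance: Optional[List[float]] = None


@dataclass
class ProtospacerPlan:
    fraction_of_spacers_from_phages: float = 0.5
    per_protospacer_mutations: int = 2


@dataclass
class HgtPlan:
    donor_phage: str
    recipient_host: str
    direct_repeat_length: int = 17
    dr_mismatches: int = 1
    gene_length: int = 600
    coverage_boost: float = 4.0
    tir_length: int = 25
    transposon_length: int = 800


@dataclass
class VariantPlan:
    background_substitution_rate: float = 0.0
    protospacer_substitution_rate: float = 0.0


@dataclass
class ReadPlan:
    read_length: int = 150
    n_reads_per_sample: List[int] = field(default_factory=lambda: [20000])
    error_rate: float = 0.0
    base_quality: int = 40


@dataclass
class CommunityConfig:
    rng_seed: int
    hosts: List[HostSpec]
    phages: List[PhageSpec]
    protospacer_plan: ProtospacerPlan = field(default_factory=ProtospacerPlan)
    hgt_plan: Optional[HgtPlan] = None
    variant_plan: VariantPlan = field(default_factory=VariantPlan)
    read_plan: ReadPlan = field(default_factory=ReadPlan)

    @property
    def n_samples(self) -> int:
        return len(self.read_plan.n_reads_per_sample)

    def validate(self) -> None:
        if self.variant_plan.protospacer_substitution_rate < (
            self.variant_plan.background_substitution_rate
        ):
            raise ValueError(
                "protospacer_substitution_rate must be >= background rate"
            )
        for ph in self.phages:
            ab = ph.per_sample_abundance
            if ab is not None and (len(ab) != self.n_samples or min(ab) < 0):
                raise ValueError(f"bad abundance vector for {ph.label}")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class PlantedSpacer:
    taxon: str
    host_id: str
    array_index: int
    spacer_seq: str
    host_interval: Interval
    source: Optional[Interval] = None  # protospacer interval on a phage


@dataclass
class PlantedArray:
    host_id: str
    taxon: str
    repeat_sequence: str
    repeat_intervals: List[Interval]
    spacer_intervals: List[Interval]


@dataclass
class HgtRecord:
    host_interval: Interval          # DR + gene copy + DR on the host
    host_gene_interval: Interval     # the inactivated gene copy alone
    donor_interval: Interval         # donor gene on the phage
    dr_sequence: str
    host_dr_intervals: List[Interval]
    phage_dr_interval: Interval
    phage_dr_sequence: str
    insertion_offset: int            # 0-based offset within the donor gene
    inserted_base: str
    premature_stop_codon: int        # codon index of the new stop
    donor_stop_codon: int
    tir_sequence: str
    tir_intervals: List[Interval]
    transposon_interval: Interval


@dataclass
class TruthTable:
    true_host_of_phage: Dict[str, str]
    taxon_of_genome: Dict[str, str]
    arrays: List[PlantedArray] = field(default_factory=list)
    planted_spacers: List[PlantedSpacer] = field(default_factory=list)
    planted_variants: List[Tuple[str, int, str, str]] = field(default_factory=list)
    protospacer_intervals: List[Interval] = field(default_factory=list)
    hgt_record: Optional[HgtRecord] = None
    read_origins: Dict[str, Dict[str, Interval]] = field(default_factory=dict)

    def spacer_set(self) -> set:
        return {s.spacer_seq for s in self.planted_spacers}

    def to_json(self, path: str) -> None:
        def default(o):
            if isinstance(o, Interval):
                return {"ref_id": o.ref_id, "start": o.start, "end": o.end,
                        "strand": o.strand}
            return asdict(o)

        payload = {
            "true_host_of_phage": self.true_host_of_phage,
            "taxon_of_genome": self.taxon_of_genome,
            "arrays": self.arrays,
            "planted_spacers": self.planted_spacers,
            "planted_variants": self.planted_variants,
            "protospacer_intervals": self.protospacer_intervals,
            "hgt_record": self.hgt_record,
            "read_origins": self.read_origins,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=default, indent=1)


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0:
        return seq
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in _BASES if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def _random_gene(rng: np.random.Generator, length: int) -> str:
    """ATG + random stop-free codons + TAA; ``length`` a multiple of 3."""
    if length % 3 or length < 300:
        raise ValueError("gene length must be a multiple of 3 and >= 300")
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = _random_seq(rng, 3)
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def translate_to_first_stop(seq: str) -> int:
    """Codon index of the first stop in frame 0, or -1 if none."""
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i // 3
    return -1


# ---------------------------------------------------------------------------
# community construction


def _place_features(
    genome: List[str], features: List[Tuple[str, str]], margin: int, gap: int
) -> Dict[str, Tuple[int, int]]:
    """Overwrite backbone segments with feature sequences, evenly spaced.

    Returns name -> (start, end).  Keeps genome length fixed so recorded
    coordinates never shift.
    """
    total = sum(len(seq) for _, seq in features)
    span = len(genome) - 2 * margin
    if total + gap * len(features) > span:
        raise ValueError("features do not fit in genome (array longer than genome?)")
    free = span - total
    step = free // (len(features) + 1)
    pos = margin + step
    placed = {}
    for name, seq in features:
        genome[pos : pos + len(seq)] = list(seq)
        placed[name] = (pos, pos + len(seq))
        pos += len(seq) + step
    return placed


def build_community(config: CommunityConfig) -> Tuple[List[SeqRecord], TruthTable]:
    """Generate host and phage genomes plus the ground-truth table.

    Host genomes contain their CRISPR arrays as ``repeat (spacer repeat)^n``
    runs at recorded intervals; the configured fraction of spacers are copied
    from phage genomes with exactly ``per_protospacer_mutations``
    substitutions.  Deterministic given ``config.rng_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    phage_seqs: Dict[str, List[str]] = {
        ph.label: list(_random_seq(rng, ph.genome_length)) for ph in config.phages
    }
    taxon_of = {h.taxon_label: h.taxon_label for h in config.hosts}
    truth = TruthTable(true_host_of_phage={}, taxon_of_genome={})

    # each phage is targeted by exactly one host taxon so the true host of a
    # phage is well defined for host-prediction scoring
    for i, ph in enumerate(config.phages):
        truth.true_host_of_phage[ph.label] = config.hosts[
            i % len(config.hosts)
        ].taxon_label
    phages_of_host: Dict[str, List[str]] = {h.taxon_label: [] for h in config.hosts}
    for ph_label, host in truth.true_host_of_phage.items():
        phages_of_host[host].append(ph_label)

    hgt = config.hgt_plan
    hgt_info: Optional[dict] = None
    if hgt is not None:
        hgt_info = _splice_donor_gene(rng, hgt, phage_seqs)

    host_records: List[SeqRecord] = []
    plan = config.protospacer_plan
    for host in config.hosts:
        genome = list(_random_seq(rng, host.genome_length))
        truth.taxon_of_genome[host.taxon_label] = host.taxon_label

        features: List[Tuple[str, str]] = []
        array_payload = []
        for ai, spec in enumerate(host.arrays):
            repeat = spec.repeat_sequence or _random_seq(rng, spec.repeat_length)
            n_phage = int(round(plan.fraction_of_spacers_from_phages * spec.n_spacers))
            sources: List[Optional[Interval]] = []
            spacers: List[str] = []
            for si in range(spec.n_spacers):
                if si < n_phage and phages_of_host[host.taxon_label]:
                    ph_label = phages_of_host[host.taxon_label][
                        rng.integers(0, len(phages_of_host[host.taxon_label]))
                    ]
                    ph_seq = phage_seqs[ph_label]
                    start = int(
                        rng.integers(0, len(ph_seq) - spec.spacer_length + 1)
                    )
                    strand = "+" if rng.random() < 0.5 else "-"
                    proto = "".join(ph_seq[start : start + spec.spacer_length])
                    spacer = proto if strand == "+" else revcomp(proto)
                    spacer = _mutate(rng, spacer, plan.per_protospacer_mutations)
                    sources.append(
                        Interval(ph_label, start, start + spec.spacer_length, strand)
                    )
                else:
                    spacer = _random_seq(rng, spec.spacer_length)
                    sources.append(None)
                spacers.append(spacer)
            array_seq = repeat + "".join(s + repeat for s in spacers)
            features.append((f"array{ai}", array_seq))
            array_payload.append((ai, repeat, spacers, sources))

        is_recipient = hgt is not None and hgt.recipient_host == host.taxon_label
        if is_recipient:
            features.append(("hgt_insert", hgt_info["host_insert"]))
            features.append(("transposon", hgt_info["transposon"]))

        placed = _place_features(genome, features, margin=1500, gap=500)

        for ai, repeat, spacers, sources in array_payload:
            a_start, _ = placed[f"array{ai}"]
            rlen = len(repeat)
            slen = len(spacers[0]) if spacers else 0
            unit = rlen + slen
            repeat_ivs = [
                Interval(host.taxon_label, a_start + k * unit,
                         a_start + k * unit + rlen)
                for k in range(len(spacers) + 1)
            ]
            spacer_ivs = []
            for k, (sp, src) in enumerate(zip(spacers, sources)):
                s0 = a_start + k * unit + rlen
                iv = Interval(host.taxon_label, s0, s0 + len(sp))
                spacer_ivs.append(iv)
                truth.planted_spacers.append(
                    PlantedSpacer(host.taxon_label, host.taxon_label, ai, sp, iv, src)
                )
                if src is not None:
                    truth.protospacer_intervals.append(src)
            truth.arrays.append(
                PlantedArray(host.taxon_label, host.taxon_label, repeat,
                             repeat_ivs, spacer_ivs)
            )

        if is_recipient:
            truth.hgt_record = _hgt_record(
                host.taxon_label, placed["hgt_insert"], placed["transposon"], hgt_info
            )

        host_records.append(SeqRecord(host.taxon_label, "".join(genome)))

    phage_records = [
        SeqRecord(ph.label, "".join(phage_seqs[ph.label])) for ph in config.phages
    ]

    _plant_variants(rng, config, phage_records, truth)
    return host_records + phage_records, truth


def _splice_donor_gene(
    rng: np.random.Generator, hgt: HgtPlan, phage_seqs: Dict[str, List[str]]
) -> dict:
    """Write the donor gene + imperfect DR into the donor phage; build the
    host-side insert (perfect DRs around a gene copy carrying one
    frame-shifting insertion) and a separate IS-like transposon cassette."""
    if hgt.donor_phage not in phage_seqs:
        raise ValueError(f"unknown donor phage {hgt.donor_phage}")
    gene = _random_gene(rng, hgt.gene_length)
    seq = phage_seqs[hgt.donor_phage]
    gene_start = len(seq) // 2
    if gene_start + len(gene) + hgt.direct_repeat_length + 10 > len(seq):
        raise ValueError("donor phage too short for the HGT gene")
    seq[gene_start : gene_start + len(gene)] = list(gene)

    # the phage's imperfect DR copy sits near, but not flush against, the
    # donor gene (in real genomes it marks a different ORF's N-terminus), so
    # repeat finders see it as a short match rather than part of the long
    # gene-to-gene alignment
    dr = _random_seq(rng, hgt.direct_repeat_length)
    phage_dr = _mutate(rng, dr, hgt.dr_mismatches)
    dr_start = gene_start - len(dr) - 150
    seq[dr_start : dr_start + len(dr)] = list(phage_dr)

    # single-base insertion creating a premature stop; inserted base differs
    # from both neighbours so the optimal gapped alignment is unambiguous
    donor_stop = len(gene) // 3 - 1
    chosen = None
    for p in range(len(gene) // 2, len(gene) - 90):
        for base in _BASES:
            if base == gene[p] or base == gene[p - 1]:
                continue
            mutant = gene[:p] + base + gene[p:]
            s = translate_to_first_stop(mutant)
            if 0 <= s < donor_stop and s > p // 3:
                chosen = (p, base, mutant, s)
                break
        if chosen:
            break
    if chosen is None:  # pragma: no cover - virtually impossible
        raise RuntimeError("could not construct a frame-shifting insertion")
    p, base, mutant, stop_codon = chosen

    host_insert = dr + mutant + dr
    tir = _random_seq(rng, hgt.tir_length)
    filler = _random_seq(rng, hgt.transposon_length - 2 * hgt.tir_length)
    transposon = tir + filler + revcomp(tir)

    return {
        "gene": gene,
        "gene_interval": Interval(hgt.donor_phage, gene_start, gene_start + len(gene)),
        "dr": dr,
        "phage_dr": phage_dr,
        "phage_dr_interval": Interval(hgt.donor_phage, dr_start, dr_start + len(dr)),
        "insertion_offset": p,
        "inserted_base": base,
        "mutant_gene": mutant,
        "premature_stop_codon": stop_codon,
        "donor_stop_codon": donor_stop,
        "host_insert": host_insert,
        "tir": tir,
        "transposon": transposon,
        "plan": hgt,
    }


def _hgt_record(
    host_id: str, insert_span: Tuple[int, int], tn_span: Tuple[int, int], info: dict
) -> HgtRecord:
    plan: HgtPlan = info["plan"]
    dlen = plan.direct_repeat_length
    s0, s1 = insert_span
    t0, t1 = tn_span
    return HgtRecord(
        host_interval=Interval(host_id, s0, s1),
        host_gene_interval=Interval(host_id, s0 + dlen, s1 - dlen),
        donor_interval=info["gene_interval"],
        dr_sequence=info["dr"],
        host_dr_intervals=[
            Interval(host_id, s0, s0 + dlen),
            Interval(host_id, s1 - dlen, s1),
        ],
        phage_dr_interval=info["phage_dr_interval"],
        phage_dr_sequence=info["phage_dr"],
        insertion_offset=info["insertion_offset"],
        inserted_base=info["inserted_base"],
        premature_stop_codon=info["premature_stop_codon"],
        donor_stop_codon=info["donor_stop_codon"],
        tir_sequence=info["tir"],
        tir_intervals=[
            Interval(host_id, t0, t0 + plan.tir_length),
            Interval(host_id, t1 - plan.tir_length, t1),
        ],
        transposon_interval=Interval(host_id, t0, t1),
    )


def _plant_variants(
    rng: np.random.Generator,
    config: CommunityConfig,
    phage_records: List[SeqRecord],
    truth: TruthTable,
) -> None:
    """Bernoulli-plant allelic variants on phage genomes: background rate
    outside protospacers, elevated rate inside them.  Variants are applied to
    simulated reads with allele frequency 0.5."""
    vp = config.variant_plan
    if vp.background_substitution_rate <= 0 and vp.protospacer_substitution_rate <= 0:
        return
    proto_by_ref: Dict[str, List[Interval]] = {}
    for iv in truth.protospacer_intervals:
        proto_by_ref.setdefault(iv.ref_id, []).append(iv)
    for rec in phage_records:
        in_proto = np.zeros(len(rec), dtype=bool)
        for iv in proto_by_ref.get(rec.id, []):
            in_proto[iv.start : iv.end] = True
        rates = np.where(
            in_proto, vp.protospacer_substitution_rate, vp.background_substitution_rate
        )
        hit = rng.random(len(rec)) < rates
        for pos in np.nonzero(hit)[0]:
            ref_base = rec.residues[pos]
            if ref_base == "N":
                continue
            alt = [b for b in _BASES if b != ref_base][rng.integers(0, 3)]
            truth.planted_variants.append((rec.id, int(pos), ref_base, alt))


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genomes: Sequence[SeqRecord],
    sample_abundances: Dict[str, Dict[str, float]],
    read_plan: ReadPlan,
    rng_seed: int,
    variants: Optional[Sequence[Tuple[str, int, str, str]]] = None,
    origin_map: Optional[Dict[str, Tuple[str, int]]] = None,
) -> Tuple[Dict[str, List[QualRead]], Dict[str, Dict[str, Interval]]]:
    """Draw uniform-error reads per sample, weighted by abundance x length.

    Reads come from either strand with probability 0.5, carry constant base
    quality and independent substitution errors at ``error_rate``.  Planted
    ``variants`` are applied per read with probability 0.5 (allele frequency
    0.5).  ``origin_map`` optionally remaps a source record id to
    ``(ref_id, offset)`` when recording truth origins (used for elevated
    copy-number sources that are slices of another genome).  Deterministic
    given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    rl = read_plan.read_length
    by_id = {g.id: g for g in genomes}
    for g in genomes:
        if len(g) < rl:
            raise ValueError(f"genome {g.id} shorter than read length")
    var_by_ref: Dict[str, List[Tuple[int, str, str]]] = {}
    for ref, pos, ref_base, alt in variants or []:
        var_by_ref.setdefault(ref, []).append((pos, ref_base, alt))
    for v in var_by_ref.values():
        v.sort()

    reads_per_sample: Dict[str, List[QualRead]] = {}
    origins: Dict[str, Dict[str, Interval]] = {}
    samples = sorted(sample_abundances)
    for si, sample in enumerate(samples):
        n_reads = read_plan.n_reads_per_sample[si]
        weights = sample_abundances[sample]
        ids = sorted(weights)
        w = np.array([weights[i] * len(by_id[i]) for i in ids], dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"sample {sample}: no positive abundance")
        counts = rng.multinomial(n_reads, w / w.sum())
        reads: List[QualRead] = []
        omap: Dict[str, Interval] = {}
        serial = 0
        for gid, count in zip(ids, counts):
            if count == 0:
                continue
            genome = by_id[gid].residues
            gvars = var_by_ref.get(gid, [])
            var_pos = np.array([p for p, _, _ in gvars], dtype=int)
            starts = rng.integers(0, len(genome) - rl + 1, size=count)
            minus = rng.random(count) < 0.5
            if read_plan.error_rate > 0:
                err_mask = rng.random((count, rl)) < read_plan.error_rate
                err_shift = rng.integers(1, 4, size=(count, rl)).astype(np.uint8)
                has_err = err_mask.any(axis=1)
            else:
                has_err = np.zeros(count, dtype=bool)
            for ridx, (start, is_minus) in enumerate(zip(starts, minus)):
                start = int(start)
                frag = genome[start : start + rl]
                if len(var_pos):
                    lo = np.searchsorted(var_pos, start)
                    hi = np.searchsorted(var_pos, start + rl)
                    if hi > lo:
                        frag_l = list(frag)
                        for vi in range(lo, hi):
                            if rng.random() < 0.5:
                                pos, _, alt = gvars[vi]
                                frag_l[pos - start] = alt
                        frag = "".join(frag_l)
                if is_minus:
                    frag = revcomp(frag)
                if has_err[ridx]:
                    # substitute by a fixed nonzero shift in code space, so
                    # the new base is uniform over the three alternatives
                    codes = encode(frag)
                    row = err_mask[ridx] & (codes < 4)
                    codes[row] = (codes[row] + err_shift[ridx][row]) % 4
                    frag = decode(codes)
                rid = f"{sample}.{serial}"
                serial += 1
                reads.append(
                    QualRead(rid, frag, [read_plan.base_quality] * rl, sample)
                )
                o_ref, o_off = gid, 0
                if origin_map and gid in origin_map:
                    o_ref, o_off = origin_map[gid]
                omap[rid] = Interval(
                    o_ref, start + o_off, start + o_off + rl,
                    "-" if is_minus else "+",
                )
        reads_per_sample[sample] = reads
        origins[sample] = omap
    return reads_per_sample, origins


def simulate_community(
    config: CommunityConfig,
) -> Tuple[List[SeqRecord], TruthTable, Dict[str, List[QualRead]]]:
    """One-shot: build genomes + truth, then simulate reads for every sample.

    When an HGT plan with ``coverage_boost > 1`` is present, an auxiliary read
    source covering the donor gene (plus 150 bp flanks) is added with weight
    ``(coverage_boost - 1)`` times the donor phage's, so the donor-gene region
    shows discretely elevated read coverage; its read origins are recorded in
    donor-phage coordinates.  Planted variants are not applied to these extra
    copies.
    """
    genomes, truth = build_community(config)
    by_id = {g.id: g for g in genomes}

    abundances: Dict[str, Dict[str, float]] = {}
    n_samples = config.n_samples
    for si in range(n_samples):
        sample = f"s{si + 1}"
        weights: Dict[str, float] = {}
        for h in config.hosts:
            ab = h.per_sample_abundance
            weights[h.taxon_label] = ab[si] if ab is not None else 1.0
        for ph in config.phages:
            ab = ph.per_sample_abundance
            weights[ph.label] = ab[si] if ab is not None else 1.0
        abundances[sample] = weights

    sources = list(genomes)
    origin_map: Dict[str, Tuple[str, int]] = {}
    hgt = config.hgt_plan
    if hgt is not None and hgt.coverage_boost > 1 and truth.hgt_record is not None:
        gene_iv = truth.hgt_record.donor_interval
        phage = by_id[gene_iv.ref_id]
        b0 = max(0, gene_iv.start - 150)
        b1 = min(len(phage), gene_iv.end + 150)
        aux_id = f"{gene_iv.ref_id}.hgt_boost"
        sources.append(SeqRecord(aux_id, phage.residues[b0:b1]))
        origin_map[aux_id] = (gene_iv.ref_id, b0)
        for sample in abundances:
            phage_w = abundances[sample][gene_iv.ref_id]
            abundances[sample][aux_id] = (hgt.coverage_boost - 1.0) * phage_w

    reads, origins = simulate_reads(
        sources,
        abundances,
        config.read_plan,
        rng_seed=int(config.rng_seed) + 1,
        variants=truth.planted_variants,
        origin_map=origin_map,
    )
    truth.read_origins = origins
    return genomes, truth, reads


def enrichment_config(rng_seed: int, rate_ratio: float) -> CommunityConfig:
    """Protospacer-diversification scenario: one 50-kb phage at ~30x depth
    carrying 240 planted protospacers (~8.2 kb targeted footprint) with
    substitution rate ``rate_ratio`` x the 0.025/bp background.

    The targeted footprint is sized so the sampling error of the recovered
    rate ratio (~1/sqrt(targeted_bp x rate)) stays well below the ratio
    itself even at ratio 1.
    """
    return CommunityConfig(
        rng_seed=rng_seed,
        hosts=[
            HostSpec(
                "hostA",
                40_000,
                [ArraySpec(n_spacers=60) for _ in range(4)],
                per_sample_abundance=[0.0],
            )
        ],
        phages=[PhageSpec("phageA", 50_000, [1.0])],
        protospacer_plan=ProtospacerPlan(1.0, 0),
        variant_plan=VariantPlan(0.025, 0.025 * rate_ratio),
        read_plan=ReadPlan(150, [10_000], 0.005, 38),
    )


def hgt_config(rng_seed: int) -> CommunityConfig:
    """Transposon-mediated HGT scenario: one host carrying the transferred
    gene copy (17-bp direct repeats, frameshift insertion) plus an IS-like
    element, one 30-kb donor phage at ~30x depth whose donor-gene region
    shows ~4x elevated coverage."""
    return CommunityConfig(
        rng_seed=rng_seed,
        hosts=[HostSpec("hostA", 40_000, [ArraySpec()], per_sample_abundance=[0.0])],
        phages=[PhageSpec("phageA", 30_000, [1.0])],
        protospacer_plan=ProtospacerPlan(0.5, 2),
        hgt_plan=HgtPlan("phageA", "hostA", coverage_boost=4.0),
        read_plan=ReadPlan(150, [7_000], 0.005, 38),
    )


def default_config(rng_seed: int = 0, **overrides) -> CommunityConfig:
    """The package's reference community: 3 hosts (2 arrays x 10 spacers
    each), 5 phages of 30 kb with sample-to-sample abundance variation over 3
    samples, half of all spacers phage-derived with 2 substitutions, an HGT
    scenario on host1/phage1, and ~20x mean coverage."""
    hosts = [
        HostSpec("host1", 40_000, [ArraySpec(), ArraySpec()]),
        HostSpec("host2", 40_000, [ArraySpec(), ArraySpec()]),
        HostSpec("host3", 40_000, [ArraySpec(), ArraySpec()]),
    ]
    phages = [
        PhageSpec("phage1", 30_000, [1.0, 0.6, 1.8]),
        PhageSpec("phage2", 30_000, [0.4, 1.5, 0.8]),
        PhageSpec("phage3", 30_000, [1.2, 0.2, 0.5]),
        PhageSpec("phage4", 30_000, [0.7, 1.0, 1.3]),
        PhageSpec("phage5", 30_000, [1.1, 0.9, 0.0]),
    ]
    cfg = CommunityConfig(
        rng_seed=rng_seed,
        hosts=hosts,
        phages=phages,
        protospacer_plan=ProtospacerPlan(0.5, 2),
        hgt_plan=HgtPlan("phage1", "host1"),
        read_plan=ReadPlan(
            read_length=150,
            n_reads_per_sample=[36_000, 36_000, 36_000],
            error_rate=0.005,
            base_quality=38,
        ),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg
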