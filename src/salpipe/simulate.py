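"""Seeded generators for every pipeline stage's input.

Each generator emulates the statistical structure its consuming stage
assumes — fragment spectra of two-acyl aminolipids with Gaussian ppm error
and uniform decoy peaks; genome cohorts with one planted causal orthologous
group; random proteins with planted catalytic motifs; log-normal abundance
tables grouped by depth zone — and emits a :class:`GeneratorTruth` carrying
the ground truth so the consuming stage can be scored without re-derivation.

Randomness is drawn from per-generator named streams
(``default_rng([seed, stream_id])``), so adding a generator never shifts
another generator's stream, and identical seed + parameters give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import (
    AcylSpec,
    Peak,
    Spectrum,
    assemble_hypothesis,
    head_ion_to_neutral,
)
from .formula import (
    add_formulas,
    format_formula,
    monoisotopic_mass,
    parse_formula,
    subtract_formulas,
)
from .motifs import AMINO_ACIDS, MOTIFS

__all__ = [
    "GeneratorTruth",
    "HOMOTAURINE",
    "simulate_lipid_spectra",
    "simulate_genomes",
    "simulate_proteins",
    "simulate_abundance",
]

# fixed stream ids: one per generator
_STREAMS = {"spectra": 11, "genomes": 23, "proteins": 37, "abundance": 41}

#: neutral aminopropane sulfonic acid (positional isomer unresolved)
HOMOTAURINE = "C3H9NO3S"


@dataclass
class GeneratorTruth:
    scenario: str
    seed: int
    payload: dict = field(default_factory=dict)


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _perturb(rng, mz: float, ppm_sigma: float) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)


def simulate_lipid_spectra(
    head_formula: str = HOMOTAURINE,
    amide_acyl: AcylSpec | None = None,
    ester_acyl: AcylSpec | None = None,
    ppm_sigma: float = 5.0,
    n_decoys: int = 20,
    seed: int = 0,
) -> tuple[list[Spectrum], GeneratorTruth]:
    """MS1/MS2/MS3 spectra of a two-acyl aminosulfonate lipid.

    The true lipid is head + amide acyl + ester acyl (condensed); the MS2
    shows the ester-acid neutral loss and the ester carboxylate anion; the
    MS3 of the residual ion shows the dehydrated deprotonated head-group ion
    and the four sulfonate diagnostics.  All m/z values carry Gaussian
    relative error of ``ppm_sigma``; decoys are uniform over the spectrum
    range; intensities are log-normal.
    """
    if ppm_sigma < 0 or n_decoys < 0:
        raise ValueError("ppm_sigma and n_decoys must be non-negative")
    amide = amide_acyl or AcylSpec(c=16, d=0, x=1, species="free_acid")
    ester = ester_acyl or AcylSpec(c=18, d=1, x=0, species="free_acid")
    if amide.species != "free_acid" or ester.species != "free_acid":
        raise ValueError("acyl specs must be given as free acids")
    head = parse_formula(head_formula)
    rng = _rng("spectra", seed)

    hyp = assemble_hypothesis(head, amide, ester, precursor_mz=0.0)
    precursor_true = hyp.theoretical_mh_minus
    residual_true = precursor_true - ester.mass()  # loss of ester free acid
    ester_anion = AcylSpec(ester.c, ester.d, ester.x, "carboxylate_anion")
    # amide-cleavage head fragment: neutral head minus 3 H (see annotate)
    head_ion = subtract_formulas(head, {"H": 3})
    head_ion_mz = monoisotopic_mass(head_ion)
    diagnostics = {ion: monoisotopic_mass(ion) for ion in ("SO3", "HSO3", "SO2", "HSO2")}

    def peak(mz, lo=1e3, hi=1e5):
        return Peak(_perturb(rng, mz, ppm_sigma), float(rng.lognormal(np.log(lo), 1.0)))

    precursor_obs = _perturb(rng, precursor_true, ppm_sigma)
    ms1 = Spectrum(level=1, peaks=(Peak(precursor_obs, 1e6),))
    ms2_peaks = [peak(residual_true, 1e5), peak(ester_anion.mass(), 1e4)]
    residual_obs = ms2_peaks[0].mz
    ms3_peaks = [peak(head_ion_mz, 1e4)] + [peak(m, 5e3) for m in diagnostics.values()]

    def decoys(n, lo, hi):
        return [Peak(float(rng.uniform(lo, hi)), float(rng.lognormal(np.log(500), 1.0)))
                for _ in range(n)]

    ms2 = Spectrum(
        level=2,
        peaks=tuple(ms2_peaks + decoys(n_decoys, 100.0, precursor_true)),
        precursor_mz=precursor_obs,
        collision_energy=40.0,
    )
    ms3 = Spectrum(
        level=3,
        peaks=tuple(ms3_peaks + decoys(n_decoys, 50.0, residual_true)),
        precursor_mz=residual_obs,
        collision_energy=90.0,
    )
    truth = GeneratorTruth(
        scenario="lipid_spectra",
        seed=seed,
        payload={
            "head_formula": format_formula(head),
            "head_ion_formula": format_formula(head_ion),
            "amide_acyl": (amide.c, amide.d, amide.x),
            "ester_acyl": (ester.c, ester.d, ester.x),
            "precursor_mz_true": precursor_true,
            "residual_mz_true": residual_true,
            "n_nitrogens": head.get("N", 0),
            "total_formula": format_formula(hyp.total_deprotonated_formula),
        },
    )
    return [ms1, ms2, ms3], truth


_BACKGROUND_ANNOTATIONS = (
    "Uncharacterized protein",
    "ABC transporter permease protein",
    "TonB-dependent receptor",
    "Two-component sensor histidine kinase",
    "MFS transporter",
    "Glutathione S-transferase",
    "Short-chain dehydrogenase reductase",
    "Outer membrane efflux protein",
    "Sigma-54 dependent transcriptional regulator",
    "Peptidase family M23",
)


def simulate_genomes(
    n_producers: int = 9,
    n_nonproducers: int = 2,
    n_background_ogs: int = 5000,
    causal_annotation: str = "acyltransferase family protein",
    n_confounders: int = 20,
    n_clade_markers: int = 36,
    background_presence: float = 0.8,
    seed: int = 0,
):
    """Gene-record table for a cohort with one planted causal OG.

    Background OGs are present in each genome independently with probability
    ``background_presence``; the causal OG sits in all producers and no
    non-producer; confounders split between near-misses (all-but-one
    producer) and leaky OGs (all producers plus one non-producer).  Clade
    markers emulate the phylogenetic signal of a real cohort — producer
    strains share ancestry, so many non-causal OGs are present in all
    producers and absent from the (basal/outgroup) non-producers; they carry
    neutral annotations, which is why a keyword filter is needed at all.
    Returns (records DataFrame, GeneratorTruth).
    """
    import pandas as pd

    if n_producers < 1:
        raise ValueError("need at least one producer genome")
    rng = _rng("genomes", seed)
    producers = [f"producer_{i:02d}" for i in range(n_producers)]
    nonproducers = [f"nonproducer_{i:02d}" for i in range(n_nonproducers)]
    genomes = producers + nonproducers

    rows = []
    gene_counter = 0

    def add(genome, og, annotation):
        nonlocal gene_counter
        gene_counter += 1
        rows.append(
            {
                "gene_id": f"gene_{gene_counter:06d}",
                "genome_id": genome,
                "og_id": og,
                "annotation": annotation,
                "cog_category": "S",
            }
        )

    for i in range(n_background_ogs):
        og = f"BG{i:05d}"
        annotation = _BACKGROUND_ANNOTATIONS[i % len(_BACKGROUND_ANNOTATIONS)]
        for genome in genomes:
            if rng.random() < background_presence:
                add(genome, og, annotation)

    causal_og = "CAUSAL00001"
    for genome in producers:
        add(genome, causal_og, causal_annotation)

    clade_markers = []
    for i in range(n_clade_markers):
        og = f"CM{i:04d}"
        clade_markers.append(og)
        annotation = _BACKGROUND_ANNOTATIONS[i % len(_BACKGROUND_ANNOTATIONS)]
        for genome in producers:
            add(genome, og, annotation)

    confounders = []
    for i in range(n_confounders):
        og = f"CF{i:04d}"
        confounders.append(og)
        if i % 2 == 0 and n_producers > 1:  # all-but-one producer
            skip = int(rng.integers(n_producers))
            for k, genome in enumerate(producers):
                if k != skip:
                    add(genome, og, "Uncharacterized protein")
        else:  # all producers plus one non-producer
            for genome in producers:
                add(genome, og, "Uncharacterized protein")
            if nonproducers:
                leak = int(rng.integers(len(nonproducers)))
                add(nonproducers[leak], og, "Uncharacterized protein")

    records = pd.DataFrame(rows)
    truth = GeneratorTruth(
        scenario="genomes",
        seed=seed,
        payload={
            "causal_og": causal_og,
            "producers": producers,
            "non_producers": nonproducers,
            "confounders": confounders,
            "clade_markers": clade_markers,
            "n_background_ogs": n_background_ogs,
        },
    )
    return records, truth


def _naive_motif_scan(seq: str):
    """Position-by-position motif occurrences, independent of the regex scanner."""
    hits = []
    for i in range(len(seq)):
        for gap, motif_id in ((4, "HX4D"), (5, "HX5D")):
            j = i + gap + 1
            if j < len(seq) and seq[i] == "H" and seq[j] == "D":
                hits.append((motif_id, i + 1, seq[i: j + 1]))
        if (
            i + 4 < len(seq)
            and seq[i] == "F"
            and seq[i + 1] == "P"
            and seq[i + 2] in "ES"
            and seq[i + 3] == "G"
            and seq[i + 4] in "TV"
        ):
            hits.append(("FPxGx", i + 1, seq[i: i + 5]))
    return sorted(hits, key=lambda h: (h[1], h[0]))


_MOTIF_TEMPLATES = {"HX4D": "H....D", "HX5D": "H.....D", "FPxGx": "FPEGT"}


def simulate_proteins(
    n: int = 10,
    length: int = 300,
    motif_plan=(),
    seed: int = 0,
):
    """Random protein sequences with motifs planted at planned positions.

    ``motif_plan`` is an iterable of (sequence index, motif id, 1-based
    start).  Wildcard positions of planted motifs are random residues that
    are re-sampled (with the +/-10 flanks) until no accidental catalytic
    motif overlaps the planted neighbourhood.  Returns
    (list of (seq_id, sequence), GeneratorTruth); the truth payload lists
    planted and accidental motif occurrences (the latter found by a naive
    position scan, so downstream scanners can be scored exactly).
    """
    rng = _rng("proteins", seed)
    plan_by_seq: dict[int, list] = {}
    for seq_idx, motif_id, start in motif_plan:
        if motif_id not in _MOTIF_TEMPLATES:
            raise ValueError(f"unknown motif id {motif_id!r}")
        template = _MOTIF_TEMPLATES[motif_id]
        if not (0 <= seq_idx < n):
            raise ValueError(f"sequence index {seq_idx} out of range")
        if start < 1 or start + len(template) - 1 > length:
            raise ValueError(
                f"motif {motif_id} at {start} does not fit in length {length}"
            )
        plan_by_seq.setdefault(seq_idx, []).append((motif_id, start, template))

    aas = np.array(list(AMINO_ACIDS))
    sequences, planted = [], []
    for idx in range(n):
        plants = plan_by_seq.get(idx, [])
        for _attempt in range(200):
            seq = list(rng.choice(aas, size=length))
            spans = []
            for motif_id, start, template in plants:
                for k, ch in enumerate(template):
                    if ch != ".":
                        seq[start - 1 + k] = ch
                spans.append((motif_id, start, start + len(template) - 1))
            text = "".join(seq)
            # accidental catalytic motifs near a plant would corrupt the truth
            planted_set = {(m, s) for m, s, _t in plants}
            clash = False
            for hit_id, pos, _span in _naive_motif_scan(text):
                if hit_id == "FPxGx" or (hit_id, pos) in planted_set:
                    continue
                if any(lo - 10 <= pos <= hi + 10 for _m, lo, hi in spans):
                    clash = True
                    break
            if not clash:
                break
        else:
            raise ValueError(f"could not satisfy motif plan for sequence {idx}")
        seq_id = f"protein_{idx:03d}"
        sequences.append((seq_id, text))
        for motif_id, start, template in plants:
            planted.append((seq_id, motif_id, start))

    accidental = []
    for seq_id, text in sequences:
        planted_here = {(m, s) for sid, m, s in planted if sid == seq_id}
        for motif_id, pos, span in _naive_motif_scan(text):
            if (motif_id, pos) not in planted_here:
                accidental.append((seq_id, motif_id, pos, span))

    truth = GeneratorTruth(
        scenario="proteins",
        seed=seed,
        payload={"planted": planted, "accidental": accidental, "length": length},
    )
    return sequences, truth


def simulate_abundance(
    zone_sizes: dict | None = None,
    zone_effects: dict | None = None,
    lognormal_params: tuple[float, float] = (2.0, 1.0),
    noise_sigma: float = 0.5,
    gene_scale: float = 0.03,
    seed: int = 0,
):
    """Per-sample marker and gene abundances grouped by depth zone.

    Marker abundances are log-normal with the given (mu, sigma) on the log
    scale; the gene abundance is median(markers) x gene_scale x zone effect x
    log-normal noise, so the normalized percentage is centred near
    ``100 x gene_scale x effect`` per zone.  Returns (DataFrame with
    sample_id, depth_zone, gene_abundance, marker_1..marker_10,
    GeneratorTruth).
    """
    import pandas as pd

    from .metag import DEPTH_ZONES, N_MARKERS

    zone_sizes = dict(zone_sizes) if zone_sizes else {z: 30 for z in DEPTH_ZONES}
    if len(zone_sizes) < 2:
        raise ValueError("need at least two depth zones")
    zone_effects = dict(zone_effects) if zone_effects else {z: 1.0 for z in zone_sizes}
    rng = _rng("abundance", seed)
    mu, sigma = lognormal_params

    rows = []
    counter = 0
    for zone, size in zone_sizes.items():
        effect = zone_effects.get(zone, 1.0)
        for _ in range(size):
            counter += 1
            markers = rng.lognormal(mu, sigma, size=N_MARKERS)
            gene = float(
                np.median(markers) * gene_scale * effect * rng.lognormal(0.0, noise_sigma)
            )
            row = {"sample_id": f"sample_{counter:04d}", "depth_zone": zone,
                   "gene_abundance": gene}
            row.update({f"marker_{k + 1}": float(m) for k, m in enumerate(markers)})
            rows.append(row)

    truth = GeneratorTruth(
        scenario="abundance",
        seed=seed,
        payload={
            "zone_sizes": zone_sizes,
            "zone_effects": zone_effects,
            "gene_scale": gene_scale,
            "noise_sigma": noise_sigma,
        },
    )
    return pd.DataFrame(rows), truth
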