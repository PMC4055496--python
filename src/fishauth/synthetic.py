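"""Synthetic study generator.

Emulates the retail survey end to end so the pipeline is testable
offline: a gadoid-like COI reference panel with controlled pairwise
divergence (congener pairs byte-identical, all cross-group divergences
above 2%), duplicate-extraction query sequences with a per-base error
rate, chimeric products (mixed species), 96-well plate fluorescence
with no-template controls and positive controls, and per-sample retail
metadata with planted mislabelling.

Sequences are generated by dropping mutations on the edges of a guide
tree reconstructed (by neighbour joining) from the requested pairwise
p-distances; every edge owns a disjoint set of sites, so realised
distances equal the summed edge counts and hit their targets to within
rounding.  Mutations are uniform over sites and substitution types.

Fluorescence follows a logistic amplification curve
``ΔRn(c) = A / (1 + exp(-(c - c50)/k))`` on wells containing a probe's
target species, plus zero-mean Gaussian cycle noise everywhere and a
constant spectral-bleed offset on non-template signals.

All randomness derives from one master seed via spawned child streams,
so a fixed configuration is byte-identical across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import taxa
from .barcode import PanelRecord, ReferencePanel
from .concordance import RuleTable, SampleRecord, default_rules
from .qpcr import PlateData
from .tree import Clade, DistanceMatrix, encode, neighbor_joining

__all__ = [
    "AmplificationModel",
    "SimulationConfig",
    "StudyData",
    "DivergenceSpecError",
    "simulate_reference_panel",
    "simulate_metadata",
    "simulate_queries",
    "simulate_plate",
    "simulate_plates",
    "simulate_study",
]

BARCODE_LENGTH = 655
_BASES = "ACGT"


class DivergenceSpecError(ValueError):
    """The requested pairwise divergences cannot be realised."""


@dataclass(frozen=True)
class AmplificationModel:
    """Logistic amplification curve parameters (fluorescence units)."""

    plateau: float = 3.0  # A
    midpoint: float = 25.0  # c50, cycles
    slope: float = 1.5  # k, cycles

    def __post_init__(self):
        if self.plateau < 0 or not (1 <= self.midpoint <= 40) or self.slope <= 0:
            raise ValueError("require A >= 0, c50 in [1, 40], k > 0")

    def curve(self, cycles: np.ndarray) -> np.ndarray:
        return self.plateau / (1.0 + np.exp(-(cycles - self.midpoint) / self.slope))


# Label vocabulary of the survey: (label on packaging, catch area).
Label = tuple[str, str]

STUDY_LABEL_DISTRIBUTION: dict[Label, float] = {
    ("Cod", "Atlantic"): 57 / 371,
    ("Cod", "Pacific"): 20 / 371,
    ("Cod", "NA"): 102 / 371,
    ("Haddock", "Atlantic"): 155 / 371,
    ("Alaskan Pollack", "Pacific"): 32 / 371,
    ("Hake (M. capensis)", "NA"): 4 / 371,
    ("Whiting", "NA"): 1 / 371,
}

# Species actually in the product when the label is truthful.
LABEL_TRUE_SPECIES: dict[str, dict[str, str]] = {
    "Cod": {
        "Atlantic": "Gadus morhua",
        "Pacific": "Gadus macrocephalus",
        "NA": "Gadus morhua",
    },
    "Haddock": {"*": "Melanogrammus aeglefinus"},
    "Alaskan Pollack": {"*": "Gadus chalcogrammus"},
    "Hake (M. capensis)": {"*": "Merluccius capensis"},
    "Whiting": {"*": "Merlangius merlangus"},
}

# Substitution probabilities conditional on the sample not being a
# chimera.  The factor rescales the survey's per-label substitution
# counts so that the *unconditional* substitution rates still match
# them after the chimeric samples (5 of 371) are set aside, keeping
# the overall planted mislabelling expectation at the survey's
# 21/371 = 5.66% (the always-substituted whiting label cannot carry
# the factor, leaving a negligible 0.004-point shortfall).
_NON_CHIMERA_COND = 371 / 366

STUDY_MISLABEL_MATRIX: dict[Label, tuple[tuple[str, float], ...]] = {
    ("Cod", "Atlantic"): (("Gadus macrocephalus", 6 / 57 * _NON_CHIMERA_COND),),
    ("Cod", "NA"): (("Melanogrammus aeglefinus", 1 / 102 * _NON_CHIMERA_COND),),
    ("Haddock", "Atlantic"): (
        ("Gadus morhua", 6 / 155 * _NON_CHIMERA_COND),
        ("Gadus macrocephalus", 1 / 155 * _NON_CHIMERA_COND),
    ),
    ("Hake (M. capensis)", "NA"): (("Merluccius paradoxus", 1 / 4 * _NON_CHIMERA_COND),),
    ("Whiting", "NA"): (("Micromesistius poutassou", 1.0),),
}

STUDY_PROCESSING_DISTRIBUTION: dict[int, float] = {
    1: 84 / 371,
    2: 84 / 371,
    3: 31 / 371,
    4: 128 / 371,
    5: 44 / 371,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic survey."""

    seed: int = 0
    n_samples: int = 371
    label_distribution: Mapping[Label, float] = field(
        default_factory=lambda: dict(STUDY_LABEL_DISTRIBUTION)
    )
    mislabel_matrix: Mapping[Label, tuple[tuple[str, float], ...]] = field(
        default_factory=lambda: dict(STUDY_MISLABEL_MATRIX)
    )
    chimera_fraction: float = 5 / 371
    chimera_mode: str = "both"  # replicates | mosaic | both
    mosaic_blend: float = 0.45
    seq_error_rate: float = 0.002
    amplification: AmplificationModel = field(default_factory=AmplificationModel)
    ntc_noise_sd: float = 0.02
    bleed_offset: float = 0.05
    processing_level_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(STUDY_PROCESSING_DISTRIBUTION)
    )

    def __post_init__(self):
        for name, dist in (
            ("label_distribution", self.label_distribution),
            ("processing_level_distribution", self.processing_level_distribution),
        ):
            total = sum(dist.values())
            if self.n_samples > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
        if not 0.0 <= self.chimera_fraction <= 1.0:
            raise ValueError("chimera_fraction must be in [0, 1]")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be a probability")
        if self.chimera_mode not in ("replicates", "mosaic", "both"):
            raise ValueError(f"unknown chimera_mode {self.chimera_mode!r}")
        for label, subs in self.mislabel_matrix.items():
            for species, p in subs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"substitution probability {p} for {label}")

    def expected_mislabel_rate(self, rules: RuleTable | None = None) -> float:
        """Analytic expectation of the planted mislabelling fraction.

        Chimeras are always mislabelled (mixed composition); a
        substitution is mislabelled when the substituted species'
        group is not acceptable for the label.
        """
        rules = rules or default_rules()
        sub_term = 0.0
        for (label, area), p_label in self.label_distribution.items():
            accept = rules.lookup(label, area).accept
            p_sub = sum(
                p
                for species, p in self.mislabel_matrix.get((label, area), ())
                if taxa.group_of(species) not in accept
            )
            sub_term += p_label * p_sub
        cf = self.chimera_fraction
        return cf + (1.0 - cf) * sub_term


def _true_species(label: str, area: str) -> str:
    spec = LABEL_TRUE_SPECIES[label]
    return spec.get(area) or spec["*"]


# ---------------------------------------------------------------------------
# Reference panel


def _edge_list(root: Clade) -> list[tuple[Clade, Clade]]:
    out = []

    def walk(node):
        for child in node.children:
            out.append((node, child))
            walk(child)

    walk(root)
    return out


def simulate_reference_panel(
    species_spec: Sequence[tuple[str, str]] | None = None,
    divergence_spec: Mapping[tuple[str, str], float] | None = None,
    length: int = BARCODE_LENGTH,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    tolerance: float = 0.005,
) -> ReferencePanel:
    """Generate a reference panel hitting target pairwise p-distances.

    ``species_spec`` lists (binomial, group id); species sharing a
    group id receive byte-identical sequences (0 divergence).
    ``divergence_spec`` maps species pairs to target p-distances in
    [0, 0.25].  Targets are realised by reconstructing a guide tree
    from the implied group-level matrix and mutating disjoint site
    sets along its edges; realised distances are verified to within
    ``tolerance``.

    Raises
    ------
    DivergenceSpecError
        If a pair at 0 divergence spans two groups, a triangle
        inequality is violated (the offending triple is reported), or
        the realised distances miss their targets.
    """
    if species_spec is None:
        species_spec = taxa.DEFAULT_SPECIES_SPEC
    if divergence_spec is None:
        divergence_spec = taxa.default_divergence_spec()
    if length < 100:
        raise ValueError("length must be >= 100")

    species = [sp for sp, _ in species_spec]
    group_of = dict(species_spec)
    groups = sorted(set(group_of.values()))

    # species-pair targets -> consistent group-pair targets
    targets: dict[tuple[str, str], float] = {}
    for (a, b), d in divergence_spec.items():
        if not 0.0 <= d <= 0.25:
            raise DivergenceSpecError(f"divergence target {d} for ({a}, {b}) outside [0, 0.25]")
        ga, gb = group_of[a], group_of[b]
        if ga == gb:
            if d != 0.0:
                raise DivergenceSpecError(
                    f"({a}, {b}) share group {ga!r} but target divergence is {d}"
                )
            continue
        if d == 0.0:
            raise DivergenceSpecError(
                f"({a}, {b}) have 0 target divergence but different groups {ga!r}/{gb!r}"
            )
        key = tuple(sorted((ga, gb)))
        if key in targets and abs(targets[key] - d) > 1e-12:
            raise DivergenceSpecError(
                f"inconsistent targets for group pair {key}: {targets[key]} vs {d}"
            )
        targets[key] = d

    for pair in itertools.combinations(groups, 2):
        if tuple(sorted(pair)) not in targets:
            raise DivergenceSpecError(f"no divergence target for group pair {pair}")

    # triangle inequality on the group matrix
    for x, y, z in itertools.combinations(groups, 3):
        dxy = targets[tuple(sorted((x, y)))]
        dxz = targets[tuple(sorted((x, z)))]
        dyz = targets[tuple(sorted((y, z)))]
        for (p, q, r), (dpq, dpr, dqr) in (
            ((x, y, z), (dxy, dxz, dyz)),
            ((y, x, z), (dxy, dyz, dxz)),
            ((z, x, y), (dxz, dyz, dxy)),
        ):
            if dpr + dqr < dpq - 1e-12:
                raise DivergenceSpecError(
                    f"triangle inequality violated for ({p}, {q}, {r}): "
                    f"d({p},{q})={dpq} > d({p},{r})+d({q},{r})={dpr + dqr}"
                )

    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    group_seqs: dict[str, np.ndarray] = {}

    if len(groups) == 1:
        group_seqs[groups[0]] = root_seq
    elif len(groups) == 2:
        d = targets[tuple(sorted(groups))]
        n_mut = int(round(d * length))
        sites = rng.choice(length, size=n_mut, replace=False)
        other = root_seq.copy()
        other[sites] = (other[sites] + rng.integers(1, 4, size=n_mut)) % 4
        group_seqs[groups[0]] = root_seq
        group_seqs[groups[1]] = other
    else:
        n = len(groups)
        D = np.zeros((n, n))
        for i, gi in enumerate(groups):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = targets[tuple(sorted((gi, groups[j])))]
        guide = neighbor_joining(DistanceMatrix(tuple(groups), D))
        edges = _edge_list(guide)
        n_sites = [int(round(e[1].length * length)) for e in edges]
        if sum(n_sites) > length:
            raise DivergenceSpecError(
                f"divergence spec needs {sum(n_sites)} mutated sites but sequences "
                f"have only {length}"
            )
        pool = rng.permutation(length)
        offsets = np.concatenate([[0], np.cumsum(n_sites)])
        site_sets = [pool[offsets[k] : offsets[k + 1]] for k in range(len(edges))]

        seqs: dict[int, np.ndarray] = {id(guide): root_seq}
        for (parent, child), sites in zip(edges, site_sets):
            seq = seqs[id(parent)].copy()
            if len(sites):
                seq[sites] = (seq[sites] + rng.integers(1, 4, size=len(sites))) % 4
            seqs[id(child)] = seq
            if child.is_leaf():
                group_seqs[child.name] = seq

    # verify realised distances against targets
    for (ga, gb), target in targets.items():
        realized = float((group_seqs[ga] != group_seqs[gb]).mean())
        if abs(realized - target) > tolerance:
            raise DivergenceSpecError(
                f"realised divergence {realized:.4f} for ({ga}, {gb}) misses "
                f"target {target:.4f} by more than {tolerance}"
            )

    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    records = [
        PanelRecord(
            record_id=f"REF{i + 1:02d}",
            species=sp,
            group=group_of[sp],
            sequence=lut[group_seqs[group_of[sp]]].tobytes().decode(),
        )
        for i, sp in enumerate(species)
    ]
    return ReferencePanel(records)


# ---------------------------------------------------------------------------
# Metadata with planted mislabelling


def simulate_metadata(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    rules: RuleTable | None = None,
) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Draw retail samples and plant mislabelling per the config.

    Returns sample records plus the truth table indexed by sample id
    (true species, chimera flags/components/mode, and whether the
    planted composition makes the label false under the rule table).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rules = rules or default_rules()
    labels = list(config.label_distribution)
    label_p = np.array([config.label_distribution[l] for l in labels])
    levels = sorted(config.processing_level_distribution)
    level_p = np.array([config.processing_level_distribution[l] for l in levels])

    n = config.n_samples
    label_idx = rng.choice(len(labels), size=n, p=label_p) if n else np.array([], int)
    level_idx = rng.choice(len(levels), size=n, p=level_p) if n else np.array([], int)
    chimera = rng.random(n) < config.chimera_fraction

    all_species = sorted({sp for sp, _ in taxa.DEFAULT_SPECIES_SPEC})
    samples: list[SampleRecord] = []
    truth_rows = []
    for i in range(n):
        sid = f"S{i + 1:04d}"
        label, area = labels[label_idx[i]]
        level = levels[level_idx[i]]
        correct = _true_species(label, area)
        correct_group = taxa.group_of(correct)
        true_species = correct
        components: tuple[str, ...] = ()
        mode = ""
        if chimera[i]:
            partners = [
                sp for sp in all_species if taxa.group_of(sp) != correct_group
            ]
            partner = partners[rng.integers(len(partners))]
            components = (correct, partner)
            if config.chimera_mode == "both":
                mode = "replicates" if rng.random() < 0.5 else "mosaic"
            else:
                mode = config.chimera_mode
        else:
            subs = config.mislabel_matrix.get((label, area), ())
            u = rng.random()
            acc = 0.0
            for species, p in subs:
                acc += p
                if u < acc:
                    true_species = species
                    break
        accept = rules.lookup(label, area).accept
        planted = bool(chimera[i]) or taxa.group_of(true_species) not in accept
        samples.append(
            SampleRecord(
                sample_id=sid,
                label_species=label,
                catch_area=area,
                processing_level=level,
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "label_species": label,
                "catch_area": area,
                "processing_level": level,
                "true_species": true_species,
                "is_chimera": bool(chimera[i]),
                "chimera_components": "+".join(components),
                "chimera_mode": mode,
                "planted_mislabel": planted,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id",
            "label_species",
            "catch_area",
            "processing_level",
            "true_species",
            "is_chimera",
            "chimera_components",
            "chimera_mode",
            "planted_mislabel",
        ],
    ).set_index("sample_id")
    return samples, truth


# ---------------------------------------------------------------------------
# Query sequences (duplicate extractions)


def _mutate(seq: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if error_rate > 0:
        n_err = rng.binomial(len(seq), error_rate)
        if n_err:
            sites = rng.choice(len(seq), size=n_err, replace=False)
            out[sites] = (out[sites] + rng.integers(1, 4, size=n_err)) % 4
    return out


def simulate_queries(
    panel: ReferencePanel,
    truth: pd.DataFrame,
    seq_error_rate: float,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    mosaic_blend: float = 0.45,
) -> dict[str, str]:
    """Two replicate extractions per sample, keyed '<sample_id>/rep<N>'.

    Non-chimeric samples yield two independent error-bearing copies of
    the true species' reference.  Chimeric samples either put a
    different component species in each replicate
    (``chimera_mode='replicates'``, emulating replicate disagreement)
    or blend the minority component's alleles into the majority
    sequence at a fraction ``mosaic_blend`` of their differing sites
    (``'mosaic'``, emulating a sub-threshold mixed trace in both
    replicates).
    """
    rng = np.random.default_rng(seed)
    ref = {rec.species: encode(rec.sequence) for rec in panel.records}
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)

    def decode(arr: np.ndarray) -> str:
        return lut[arr].tobytes().decode()

    out: dict[str, str] = {}
    for sid, row in truth.iterrows():
        if row["is_chimera"]:
            components = row["chimera_components"].split("+")
            if len(components) < 2:
                raise ValueError(
                    f"sample {sid}: chimera needs >= 2 component species, got {components}"
                )
            a, b = ref[components[0]], ref[components[1]]
            if row["chimera_mode"] == "replicates":
                templates = [a, b]
            else:  # mosaic: blend minority alleles into the majority strand
                mosaic = a.copy()
                diff = np.flatnonzero(a != b)
                picked = diff[rng.random(len(diff)) < mosaic_blend]
                mosaic[picked] = b[picked]
                templates = [mosaic, mosaic]
        else:
            template = ref[row["true_species"]]
            templates = [template, template]
        for r, template in enumerate(templates, start=1):
            out[f"{sid}/rep{r}"] = decode(_mutate(template, seq_error_rate, rng))
    return out


# ---------------------------------------------------------------------------
# Plates


def _well_names() -> list[str]:
    return [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


SAMPLES_PER_PLATE = 84  # 96 wells - 8 NTC - 4 positive controls


def simulate_plate(
    samples: Sequence[SampleRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    plate_id: str = "P1",
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    n_ntc: int = 8,
) -> PlateData:
    """One 96-well plate: 8 NTCs, 2+2 positive controls, <= 84 samples."""
    if n_ntc < 8:
        raise ValueError(f"a plate requires >= 8 NTC wells, got {n_ntc}")
    if len(samples) > SAMPLES_PER_PLATE:
        raise ValueError(
            f"{len(samples)} samples exceed plate capacity {SAMPLES_PER_PLATE}; "
            "use simulate_plates to split across plates"
        )
    rng = np.random.default_rng(seed)
    dye_targets = dict(taxa.DYE_TARGETS)
    wells = _well_names()

    layout: list[tuple[str, str, str, frozenset[str]]] = []  # well, role, sample_id, template species
    w = iter(wells)
    for _ in range(n_ntc):
        layout.append((next(w), "NTC", "", frozenset()))
    for _ in range(2):
        layout.append((next(w), "POS_COD", "", frozenset({dye_targets["COD"]})))
    for _ in range(2):
        layout.append((next(w), "POS_HAD", "", frozenset({dye_targets["HAD"]})))
    for s in samples:
        row = truth.loc[s.sample_id]
        if row["is_chimera"]:
            species = frozenset(row["chimera_components"].split("+"))
        else:
            species = frozenset({row["true_species"]})
        layout.append((next(w), "SAMPLE", s.sample_id, species))

    cycles = np.arange(1, 41)
    amp = config.amplification.curve(cycles)
    dyes = sorted(dye_targets)
    n_traj = len(layout) * len(dyes)
    noise = rng.normal(0.0, config.ntc_noise_sd, size=(n_traj, len(cycles)))

    frames = []
    t = 0
    for well, role, sample_id, species in layout:
        for dye in dyes:
            target_present = dye_targets[dye] in species
            base = amp if target_present else config.bleed_offset
            values = base + noise[t]
            frames.append(
                pd.DataFrame(
                    {
                        "well": well,
                        "role": role,
                        "sample_id": sample_id,
                        "dye": dye,
                        "cycle": cycles,
                        "delta_rn": values,
                    }
                )
            )
            t += 1
    return PlateData(plate_id, pd.concat(frames, ignore_index=True), dye_targets)


def simulate_plates(
    samples: Sequence[SampleRecord],
    truth: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> list[PlateData]:
    """Split samples across as many 96-well plates as needed."""
    if isinstance(seed, np.random.Generator):
        raise TypeError("simulate_plates needs an int or SeedSequence seed")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chunks = [
        samples[i : i + SAMPLES_PER_PLATE]
        for i in range(0, len(samples), SAMPLES_PER_PLATE)
    ] or [[]]
    children = ss.spawn(len(chunks))
    return [
        simulate_plate(chunk, truth, config, plate_id=f"P{k + 1}", seed=children[k])
        for k, chunk in enumerate(chunks)
    ]


# ---------------------------------------------------------------------------
# Whole study


@dataclass
class StudyData:
    config: SimulationConfig
    samples: list[SampleRecord]
    truth: pd.DataFrame
    panel: ReferencePanel
    queries: dict[str, str]
    plates: list[PlateData]

    def write(self, outdir) -> None:
        """Write panel/query FASTA, plate CSV and metadata TSV."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.panel.to_fasta(outdir / "reference_panel.fasta")
        with open(outdir / "queries.fasta", "w") as fh:
            for qid in sorted(self.queries):
                fh.write(f">{qid}\n")
                seq = self.queries[qid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        frames = []
        for plate in self.plates:
            df = plate.df.copy()
            df.insert(0, "plate_id", plate.plate_id)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "plates.csv", index=False, float_format="%.6g"
        )
        meta = self.truth.reset_index()[
            [
                "sample_id",
                "label_species",
                "catch_area",
                "processing_level",
                "true_species",
                "is_chimera",
            ]
        ]
        meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate a complete synthetic survey under one master seed."""
    ss = np.random.SeedSequence(config.seed)
    s_panel, s_meta, s_query, s_plate = ss.spawn(4)
    panel = simulate_reference_panel(seed=s_panel)
    samples, truth = simulate_metadata(config, seed=s_meta)
    queries = simulate_queries(
        panel,
        truth,
        config.seq_error_rate,
        seed=s_query,
        mosaic_blend=config.mosaic_blend,
    )
    plates = simulate_plates(samples, truth, config, seed=s_plate)
    return StudyData(
        config=config,
        samples=samples,
        truth=truth,
        panel=panel,
        queries=queries,
        plates=plates,
    )
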