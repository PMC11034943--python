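"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generators emulate the data structures of a diagnosis/relapse AML study:

- a mutation meta-analysis cohort with per-patient clonal bins (Stable /
  Gain / Loss / GainAndLoss) planted via the VAF dynamics of each mutation,
  plus clinical covariates in which clonally stable patients relapse faster;
- bulk ATAC peak count matrices (negative-binomial noise around per-patient
  baselines, two technical replicates per sample) with a planted
  relapse-shifted signature;
- a cell-type-structured healthy hematopoietic single-cell reference in
  which each type carries a private block of accessible peaks and hierarchy
  edges create graded similarity;
- mitochondrial scATAC allele counts drawn from a planted clone tree with
  binomial heteroplasmy sampling, optional strand-artifact variants, and a
  "convergence" mode that moves all relapse clones toward one shared
  chromatin profile.

Every generator is a pure function of its configuration (including the
seed): identical inputs give identical outputs, and planted truth is always
returned alongside the data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as eio

AML_GENES = [
    "NPM1", "DNMT3A", "FLT3", "RUNX1", "TET2", "WT1", "IDH1", "IDH2",
    "NRAS", "KRAS", "PTPN11", "ASXL1", "TP53", "CEBPA", "SRSF2", "U2AF1",
]

DEFAULT_CELLTYPES: list[tuple[str, str | None]] = [
    ("HSC", None),
    ("Progenitor", "HSC"),
    ("Myeloid", "Progenitor"),
    ("Lymphoid", "Progenitor"),
]

# (clone, parent, defining variants, freq at diagnosis, freq at relapse)
DEFAULT_CLONE_TREE: list[tuple[str, str | None, tuple[str, ...], float, float]] = [
    ("clone1", None, ("m1",), 0.5, 0.4),
    ("clone2", "clone1", ("m1", "m2"), 0.3, 0.3),
    ("clone3", "clone1", ("m1", "m3"), 0.2, 0.3),
]

BIN_NAMES = ["Stable", "Gain", "Loss", "GainAndLoss"]


@dataclass
class SimConfig:
    """Study conditions for all generators.

    ``bin_probabilities`` follows the meta-analysis cohort (43% Stable);
    relapse times are exponential with the stable-bin hazard 1.56x the
    unstable hazard, so the survival stage has a planted effect of the
    reported size. Chromatin dimensions default to a scaled-down peak
    universe (20,000 peaks) with a 500-feature relapse signature shifted by
    one log2 unit.
    """

    seed: int = 0
    n_patients: int = 216
    bin_probabilities: tuple[float, float, float, float] = (0.43, 0.20, 0.17, 0.20)
    n_peaks: int = 20_000
    n_genes: int = 2_000
    signature_size: int = 500
    effect_log2fc: float = 1.0
    nb_dispersion: float = 0.1
    n_bulk_patients: int = 10
    mean_peak_count: float = 30.0
    celltypes: list[tuple[str, str | None]] = field(
        default_factory=lambda: list(DEFAULT_CELLTYPES))
    cells_per_type: int = 100
    mean_reads_per_cell: float = 2_000.0
    clone_tree_spec: list[tuple[str, str | None, tuple[str, ...], float, float]] = field(
        default_factory=lambda: list(DEFAULT_CLONE_TREE))
    mean_mito_coverage: float = 20.0
    mito_coverage_dispersion: float = 0.5
    heteroplasmy: float = 0.9
    heteroplasmy_levels: dict[tuple[str, str], float] = field(default_factory=dict)
    n_cells_per_timepoint: int = 1_000
    n_artifact_variants: int = 2
    convergence: bool = False
    convergence_weight: float = 0.8
    clone_program_sd: float = 0.5
    relapse_scale_days: float = 400.0
    stable_hazard_ratio: float = 1.56
    censoring_fraction: float = 0.15

    def __post_init__(self) -> None:
        probs = np.asarray(self.bin_probabilities, dtype=float)
        if probs.shape != (4,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("bin_probabilities must be a 4-vector summing to 1")
        if self.nb_dispersion <= 0 or self.mean_mito_coverage <= 0:
            raise ValueError("rates and dispersions must be positive")
        if self.signature_size > self.n_peaks:
            raise ValueError("signature_size cannot exceed n_peaks")
        if not 0.0 <= self.heteroplasmy <= 1.0:
            raise ValueError("heteroplasmy must lie in [0, 1]")
        self._validate_clone_tree()

    def _validate_clone_tree(self) -> None:
        names = [c[0] for c in self.clone_tree_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clone names")
        parents = {c[0]: c[1] for c in self.clone_tree_spec}
        variants = {c[0]: set(c[2]) for c in self.clone_tree_spec}
        for clone, parent in parents.items():
            seen = {clone}
            p = parent
            while p is not None:
                if p in seen:
                    raise ValueError("clone tree spec contains a cycle")
                if p not in parents:
                    raise ValueError(f"unknown parent {p}")
                seen.add(p)
                p = parents[p]
            if parent is not None and not variants[parent] <= variants[clone]:
                raise ValueError(f"clone {clone} does not inherit its parent's variants")
        for j, label in ((3, "diagnosis"), (4, "relapse")):
            tot = sum(c[j] for c in self.clone_tree_spec)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"{label} clone frequencies must sum to 1")


# ---------------------------------------------------------------------------
# mutation cohort


def _draw_vafs(rng: np.random.Generator, cls: str) -> tuple[float, float]:
    if cls == "gained":
        return rng.uniform(0.0, 0.045), rng.uniform(0.12, 0.5)
    if cls == "lost":
        return rng.uniform(0.12, 0.5), rng.uniform(0.0, 0.045)
    v = rng.uniform(0.12, 0.45)
    return v, float(np.clip(v + rng.normal(0, 0.03), 0.105, 0.5))


def simulate_mutation_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Mutation + clinical tables with planted bins and mutation classes.

    Each patient carries 1-8 mutations whose VAF dynamics force the planted
    class under the 0.05/0.1 threshold rule; roughly one in ten mutations is
    a non-quantifiable FLT3-ITD/NPM1-type event carried as presence flags.
    Stable-bin patients draw shorter exponential relapse times (hazard ratio
    ``stable_hazard_ratio``).
    """
    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.bin_probabilities, dtype=float)
    mut_rows, clin_rows = [], []
    truth_bins, truth_classes = {}, {}
    for i in range(config.n_patients):
        pid = f"PT{i:04d}"
        b = BIN_NAMES[rng.choice(4, p=probs)]
        n_mut = int(rng.integers(1, 9))
        classes = ["stable"] * n_mut
        if b == "Gain":
            classes[0] = "gained"
            for j in range(1, n_mut):
                if rng.random() < 0.3:
                    classes[j] = "gained"
        elif b == "Loss":
            classes[0] = "lost"
            for j in range(1, n_mut):
                if rng.random() < 0.3:
                    classes[j] = "lost"
        elif b == "GainAndLoss":
            if n_mut == 1:
                n_mut = 2
                classes = ["stable", "stable"]
            classes[0], classes[1] = "gained", "lost"
            for j in range(2, n_mut):
                if rng.random() < 0.3:
                    classes[j] = rng.choice(["gained", "lost"])
        genes = rng.choice(AML_GENES, size=n_mut, replace=False if n_mut <= len(AML_GENES) else True)
        for j, cls in enumerate(classes):
            gene = str(genes[j])
            quant = not (gene in ("FLT3", "NPM1") and rng.random() < 0.5)
            vid = f"{pid}_var{j}"
            if quant:
                vd, vr = _draw_vafs(rng, cls)
                row = dict(patient_id=pid, gene=gene, variant_id=vid,
                           vaf_dx=round(vd, 4), vaf_rel=round(vr, 4),
                           quantifiable=True, present_dx=pd.NA, present_rel=pd.NA,
                           tier=int(rng.integers(1, 3)))
            else:
                p_dx = cls != "gained"
                p_rel = cls != "lost"
                row = dict(patient_id=pid, gene=gene, variant_id=vid,
                           vaf_dx=np.nan, vaf_rel=np.nan, quantifiable=False,
                           present_dx=p_dx, present_rel=p_rel,
                           tier=int(rng.integers(1, 3)))
            mut_rows.append(row)
            truth_classes[vid] = cls
        truth_bins[pid] = b

        age = float(np.clip(rng.normal(60, 10), 18, 90))
        sex = "M" if rng.random() < 0.5 else "F"
        scale = (config.relapse_scale_days / config.stable_hazard_ratio
                 if b == "Stable" else config.relapse_scale_days)
        t = rng.exponential(scale)
        if rng.random() < config.censoring_fraction:
            t, event = rng.uniform(0, t), False
        else:
            event = True
        clin_rows.append(dict(patient_id=pid, age=round(age, 1), sex=sex,
                              days_to_relapse=round(max(t, 1.0), 1),
                              relapse_event=event))
    mutations = pd.DataFrame(mut_rows)
    clinical = pd.DataFrame(clin_rows)
    truth = {"patient_bins": pd.Series(truth_bins, name="bin"),
             "mutation_classes": pd.Series(truth_classes, name="dynamics")}
    return mutations, clinical, truth


# ---------------------------------------------------------------------------
# bulk chromatin cohort


def synthetic_peaks(n_peaks: int, width: int = 500, spacing: int = 2_000,
                    peaks_per_chrom: int = 5_000) -> pd.DataFrame:
    """Evenly spaced fixed-width peaks on synthetic chromosomes."""
    rows = []
    for i in range(n_peaks):
        chrom = f"chr{i // peaks_per_chrom + 1}"
        start = (i % peaks_per_chrom) * spacing + 1_000
        rows.append({"chrom": chrom, "start": start, "end": start + width})
    df = pd.DataFrame(rows)
    df["name"] = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    return df


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_bulk_chromatin_cohort(
    config: SimConfig, signature_patients: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Peak x sample counts for a diagnosis/relapse bulk ATAC cohort.

    Negative-binomial counts around lognormal per-peak baselines modulated by
    a per-patient factor; two technical replicates per (patient, timepoint).
    The first ``signature_size`` peaks are shifted by ``effect_log2fc`` at
    relapse in the designated patients (all patients by default). Returns
    (counts, sample metadata, truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    peaks = synthetic_peaks(config.n_peaks)
    base = rng.lognormal(np.log(config.mean_peak_count), 1.0, config.n_peaks)
    patients = [f"BP{i:02d}" for i in range(config.n_bulk_patients)]
    if signature_patients is None:
        signature_patients = patients
    sig_idx = np.arange(config.signature_size)
    fold = 2.0 ** config.effect_log2fc

    cols, meta = {}, []
    for pid in patients:
        pat_eff = rng.lognormal(0.0, 0.2)
        for tp in ("diagnosis", "relapse"):
            mean = base * pat_eff
            if tp == "relapse" and pid in signature_patients:
                mean = mean.copy()
                mean[sig_idx] *= fold
            for rep in (1, 2):
                name = f"{pid}_{tp}_r{rep}"
                cols[name] = _nb_draw(rng, mean, config.nb_dispersion)
                meta.append({"sample": name, "patient_id": pid,
                             "timepoint": tp, "replicate": rep})
    counts = pd.DataFrame(cols, index=peaks["name"])
    truth = {"signature_features": list(peaks["name"].iloc[sig_idx]),
             "signature_patients": list(signature_patients),
             "peaks": peaks}
    return counts, pd.DataFrame(meta), truth


def simulate_fragments(
    peaks: pd.DataFrame, n_fragments: int, seed: int = 0,
    weights: np.ndarray | None = None, barcode: str = "bulk",
) -> pd.DataFrame:
    """Fragments whose Tn5 cut sites fall inside the given peaks.

    Peak choice follows ``weights`` (uniform by default); fragment ends are
    placed so both shifted cut sites stay inside the 0-based half-open peak.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(weights, dtype=float) if weights is not None else np.ones(len(peaks))
    w = w / w.sum()
    idx = rng.choice(len(peaks), size=n_fragments, p=w)
    starts = peaks["start"].to_numpy()[idx] + rng.integers(0, 150, n_fragments)
    lengths = rng.integers(60, 250, n_fragments)
    ends = starts + lengths
    return pd.DataFrame({
        "chrom": peaks["chrom"].to_numpy()[idx],
        "start": starts, "end": ends,
        "barcode": barcode, "count": 1,
    }).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# healthy reference


def _celltype_programs(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-type peak accessibility rates: shared housekeeping background plus
    inherited + private enriched blocks."""
    types = config.celltypes
    if len(types) < 1:
        raise ValueError("need at least one cell type")
    n_private = max(config.n_peaks // (3 * len(types)), 1)
    housekeeping = rng.uniform(0.5, 1.5, config.n_peaks)
    blocks = {}
    offset = 0
    for name, _ in types:
        blocks[name] = np.arange(offset, min(offset + n_private, config.n_peaks))
        offset += n_private
    parents = dict(types)
    programs = {}
    for name, _ in types:
        prog = housekeeping.copy()
        lineage = [name]
        p = parents[name]
        while p is not None:
            lineage.append(p)
            p = parents[p]
        for depth, anc in enumerate(lineage):
            prog[blocks[anc]] += 8.0 / (1 + depth)  # own block strongest
        programs[name] = prog
    return programs


def simulate_reference_hematopoiesis(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Cell x peak counts for a healthy reference with labeled cell types.

    Each type carries a private block of enriched peaks on top of shared
    housekeeping accessibility; a child type inherits its ancestors' blocks
    at decaying strength, so parents sit between their children in profile
    space. Per-cell counts are multinomial draws at Poisson depth.
    """
    rng = np.random.default_rng(config.seed + 2)
    programs = _celltype_programs(config, rng)
    peak_ids = synthetic_peaks(config.n_peaks)["name"]
    rows, labels, names = [], [], []
    for tname, prog in programs.items():
        p = prog / prog.sum()
        for c in range(config.cells_per_type):
            depth = max(int(rng.poisson(config.mean_reads_per_cell)), 50)
            rows.append(rng.multinomial(depth, p))
            cell = f"{tname}_{c}"
            names.append(cell)
            labels.append(tname)
    counts = pd.DataFrame(np.vstack(rows), index=names, columns=peak_ids)
    return counts, pd.Series(labels, index=names, name="celltype")


# ---------------------------------------------------------------------------
# mitochondrial scATAC


def _clone_variants(config: SimConfig) -> tuple[list[str], dict[str, set[str]]]:
    variants: list[str] = []
    per_clone: dict[str, set[str]] = {}
    for clone, _, defs, _, _ in config.clone_tree_spec:
        per_clone[clone] = set(defs)
        for v in defs:
            if v not in variants:
                variants.append(v)
    return variants, per_clone


def simulate_mito_scatac(config: SimConfig) -> dict:
    """Strand-split mitochondrial allele counts plus chromatin counts drawn
    from a planted clone tree.

    Each cell's alt reads at a clone variant are Binomial(coverage,
    heteroplasmy); reads split evenly between strands. Planted artifact
    variants put each cell's alt reads on a single strand, breaking the
    strand correlation the variant QC requires. Clone chromatin programs get
    private blocks; in convergence mode every clone's relapse program is
    pulled toward one shared relapse profile by ``convergence_weight``.
    """
    rng = np.random.default_rng(config.seed + 3)
    variants, per_clone = _clone_variants(config)
    artifact_variants = [f"art{i}" for i in range(config.n_artifact_variants)]
    all_variants = variants + artifact_variants
    clones = [c[0] for c in config.clone_tree_spec]
    freq = {"diagnosis": np.array([c[3] for c in config.clone_tree_spec]),
            "relapse": np.array([c[4] for c in config.clone_tree_spec])}

    cell_ids, cell_clone, cell_tp = [], [], []
    for tp in ("diagnosis", "relapse"):
        assign = rng.choice(len(clones), size=config.n_cells_per_timepoint, p=freq[tp])
        for i, a in enumerate(assign):
            cell_ids.append(f"{tp[:3]}_{i}")
            cell_clone.append(clones[a])
            cell_tp.append(tp)
    n_cells = len(cell_ids)

    shape = (len(all_variants), n_cells)
    alt_fw = np.zeros(shape, dtype=np.int64)
    alt_rev = np.zeros(shape, dtype=np.int64)
    ref_fw = np.zeros(shape, dtype=np.int64)
    ref_rev = np.zeros(shape, dtype=np.int64)
    for vi, v in enumerate(all_variants):
        # negative-binomial per-cell coverage: the cell-to-cell depth
        # variation shared by both strands is what gives true variants their
        # positive strand correlation
        cov = _nb_draw(rng, np.full(n_cells, config.mean_mito_coverage),
                       config.mito_coverage_dispersion)
        if v in artifact_variants:
            het = np.where(rng.random(n_cells) < 0.5, 0.3, 0.0)
        else:
            het = np.array([
                config.heteroplasmy_levels.get(
                    (cl, v), config.heteroplasmy if v in per_clone[cl] else 0.0)
                for cl in cell_clone])
        alt = rng.binomial(cov, het)
        ref = cov - alt
        if v in artifact_variants:
            # all alt reads land on one strand per cell
            on_fw = rng.random(n_cells) < 0.5
            alt_fw[vi] = np.where(on_fw, alt, 0)
            alt_rev[vi] = np.where(on_fw, 0, alt)
        else:
            alt_fw[vi] = rng.binomial(alt, 0.5)
            alt_rev[vi] = alt - alt_fw[vi]
        ref_fw[vi] = rng.binomial(ref, 0.5)
        ref_rev[vi] = ref - ref_fw[vi]

    def _df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=all_variants, columns=cell_ids)

    # clone chromatin programs
    base = rng.lognormal(0.0, 1.0, config.n_peaks)
    n_block = max(config.n_peaks // (3 * len(clones)), 1)
    clone_block = {cl: np.arange(i * n_block, min((i + 1) * n_block, config.n_peaks))
                   for i, cl in enumerate(clones)}
    shared_relapse = base * rng.lognormal(0.0, config.clone_program_sd, config.n_peaks)
    programs: dict[tuple[str, str], np.ndarray] = {}
    for cl in clones:
        prog = base.copy()
        prog[clone_block[cl]] *= 2.0 ** (2.0 * config.clone_program_sd)
        programs[(cl, "diagnosis")] = prog
        if config.convergence:
            w = config.convergence_weight
            programs[(cl, "relapse")] = (1 - w) * prog + w * shared_relapse
        else:
            programs[(cl, "relapse")] = prog

    peak_ids = synthetic_peaks(config.n_peaks)["name"]
    counts = np.zeros((n_cells, config.n_peaks), dtype=np.int64)
    for i in range(n_cells):
        prog = programs[(cell_clone[i], cell_tp[i])]
        p = prog / prog.sum()
        depth = max(int(rng.poisson(config.mean_reads_per_cell)), 50)
        counts[i] = rng.multinomial(depth, p)
    cell_peak_counts = pd.DataFrame(counts, index=cell_ids, columns=peak_ids)

    assignments = pd.DataFrame({"cell": cell_ids, "clone": cell_clone,
                                "timepoint": cell_tp})
    truth_parents = {c[0]: c[1] for c in config.clone_tree_spec}
    return {
        "alt_fw": _df(alt_fw), "alt_rev": _df(alt_rev),
        "ref_fw": _df(ref_fw), "ref_rev": _df(ref_rev),
        "cell_peak_counts": cell_peak_counts,
        "assignments": assignments,
        "truth_tree": {"parents": truth_parents,
                       "defining_variants": {c: frozenset(v) for c, v in per_clone.items()}},
        "artifact_variants": artifact_variants,
        "clone_variants": variants,
    }


def make_clone_tree_spec(
    n_clones: int, seed: int = 0,
    freq_dx: list[float] | None = None, freq_rel: list[float] | None = None,
) -> list[tuple[str, str | None, tuple[str, ...], float, float]]:
    """Random rooted clone tree spec with inherited defining variants.

    Clone ``i`` attaches to a random earlier clone and adds one private
    variant on top of its parent's set. Frequencies default to a flat
    Dirichlet draw (concentration 5, so no clone is vanishingly rare).
    """
    rng = np.random.default_rng(seed)
    names = [f"clone{i + 1}" for i in range(n_clones)]
    parents: list[str | None] = [None]
    varsets: list[tuple[str, ...]] = [("m1",)]
    for i in range(1, n_clones):
        j = int(rng.integers(0, i))
        parents.append(names[j])
        varsets.append(tuple(sorted(set(varsets[j]) | {f"m{i + 1}"})))
    if freq_dx is None:
        freq_dx = rng.dirichlet(np.full(n_clones, 5.0)).tolist()
    if freq_rel is None:
        freq_rel = rng.dirichlet(np.full(n_clones, 5.0)).tolist()
    freq_dx = (np.asarray(freq_dx) / np.sum(freq_dx)).tolist()
    freq_rel = (np.asarray(freq_rel) / np.sum(freq_rel)).tolist()
    return [(names[i], parents[i], varsets[i], freq_dx[i], freq_rel[i])
            for i in range(n_clones)]


# ---------------------------------------------------------------------------
# gene models and gene sets


def simulate_gene_models(config: SimConfig, gene_spacing: int = 60_000,
                         gene_length: int = 20_000) -> pd.DataFrame:
    """Non-overlapping gene models on synthetic chromosomes (BED-like)."""
    rng = np.random.default_rng(config.seed + 4)
    rows = []
    per_chrom = 500
    for i in range(config.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * gene_spacing + 30_000
        rows.append({"gene": f"G{i:04d}", "chrom": chrom, "start": start,
                     "end": start + gene_length,
                     "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows)


def simulate_gene_sets(
    genes: list[str], n_sets: int = 10, set_size: int = 30, seed: int = 0,
    planted_top: list[str] | None = None,
) -> dict[str, list[str]]:
    """Random gene sets, optionally including one set drawn from a planted
    top-gene list (named ``PLANTED_SET``)."""
    rng = np.random.default_rng(seed)
    sets = {f"RANDOM_SET_{i}": list(rng.choice(genes, size=set_size, replace=False))
            for i in range(n_sets)}
    if planted_top:
        k = min(set_size, len(planted_top))
        sets["PLANTED_SET"] = list(rng.choice(planted_top, size=k, replace=False))
    return sets


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(outputs: dict, directory: str) -> dict[str, int]:
    """Write generated objects as the plain-text exchange formats.

    Recognized keys: ``mutations``/``clinical``/``assignments`` and any
    other DataFrame (TSV with header), ``fragments`` (5-column
    fragments.tsv), ``peaks``/``blacklist`` (BED), ``*_counts`` DataFrames
    (MTX triplet), ``gene_sets`` (GMT). Returns (and writes) a
    {file: row count} manifest.
    """
    os.makedirs(directory, exist_ok=True)
    manifest: dict[str, int] = {}
    for key, obj in outputs.items():
        if key == "fragments":
            path = os.path.join(directory, "fragments.tsv")
            eio.write_fragments(obj, path)
            manifest["fragments.tsv"] = len(obj)
        elif key in ("peaks", "blacklist"):
            fname = f"{key}.bed"
            eio.write_bed(obj, os.path.join(directory, fname))
            manifest[fname] = len(obj)
        elif key == "gene_sets":
            eio.write_gmt(obj, os.path.join(directory, "gene_sets.gmt"))
            manifest["gene_sets.gmt"] = len(obj)
        elif key.endswith("_counts"):
            sub = os.path.join(directory, key)
            eio.write_count_matrix(obj, sub)
            manifest[f"{key}/matrix.mtx"] = int(obj.shape[0])
        elif isinstance(obj, pd.DataFrame):
            fname = f"{key}.tsv"
            obj.to_csv(os.path.join(directory, fname), sep="\t", index=False)
            manifest[fname] = len(obj)
        elif isinstance(obj, pd.Series):
            fname = f"{key}.tsv"
            obj.rename_axis("id").reset_index().to_csv(
                os.path.join(directory, fname), sep="\t", index=False)
            manifest[fname] = len(obj)
        else:
            raise TypeError(f"cannot serialize fixture entry {key!r}")
    eio.write_manifest(manifest, os.path.join(directory, "manifest.json"))
    return manifest
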