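"""Synthetic cfDNA cohorts under a nucleosome-footprint coverage model.

Plasma cfDNA is modelled as a two-tissue mixture: a fraction
``placental_fraction`` (default 0.10) of fragments originates from the
placenta track, the rest from the maternal whole-blood track.  Each tissue
imprints its transcriptional activity on fragment density: around the TSS
of an active gene, fragment (midpoint) intensity is thinned by an inverted
Gaussian dip of relative depth ``activity * depletion_depth``, emulating
the nucleosome-depleted promoter of an expressed gene whose exposed DNA is
digested before entering circulation.  Unexpressed genes leave a flat
profile.

Case/control cohorts can carry planted differential promoters: in case
samples the fragment intensity over each planted pTSS window is boosted by
a factor 2**effect_lfc, so the expected case/control window-count ratio —
and hence the expected log2 fold change recovered downstream — equals
``effect_lfc`` by construction.

Fragment lengths follow a truncated Normal(167, 20) on [50, 400] bp, the
canonical mononucleosome cfDNA mode.  Every sample contains exactly
``fragments_per_sample`` fragments, all on declared chromosomes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptModel
from .coverage import FragmentSet

logger = logging.getLogger("promoterfoot")

__all__ = [
    "GeneUniverse",
    "OccupancyModel",
    "CohortSpec",
    "simulate_gene_universe",
    "simulate_sample_fragments",
    "simulate_cohort",
    "write_fixtures",
    "activity_from_expression",
]

_TISSUES = ("placenta", "blood")
#: gene body length used when exporting transcript spans (bp)
_TX_BODY = 2000
#: margin between chromosome ends and the first/last TSS (bp)
_EDGE_MARGIN = 50_000
#: pTSS flank assumed when widening the planted-boost region (bp)
_PTSS_FLANK = 1000


@dataclass
class GeneUniverse:
    """Transcripts, per-tissue expression, and named gene sets.

    One transcript per gene.  ``transcripts`` columns: transcript_id,
    gene_symbol, chrom, strand, tss, tx_start, tx_end.  ``expression`` is
    indexed by transcript_id with columns placenta and blood (arbitrary
    nonnegative units).
    """

    transcripts: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: dict[str, list[str]]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        ids = self.transcripts["transcript_id"]
        if not ids.is_unique:
            raise ValueError("transcript ids must be unique")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression must be nonnegative")
        known = set(ids)
        for name, members in self.gene_sets.items():
            missing = set(members) - known
            if missing:
                raise ValueError(f"gene set {name!r} has unknown members: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.transcripts)

    def to_transcript_models(self) -> list[TranscriptModel]:
        return [
            TranscriptModel(
                transcript_id=row.transcript_id,
                gene_symbol=row.gene_symbol,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
            )
            for row in self.transcripts.itertuples(index=False)
        ]


def activity_from_expression(universe: GeneUniverse) -> pd.DataFrame:
    """Map expression rank to promoter activity in [0, 1] per tissue.

    Among expressed genes (expression > 0), activity is the fractional
    rank of the gene's expression in that tissue (highest-expressed -> 1);
    unexpressed genes have activity 0.
    """
    act = {}
    for tissue in _TISSUES:
        expr = universe.expression[tissue].to_numpy(dtype=float)
        a = np.zeros(len(expr))
        pos = expr > 0
        if pos.any():
            ranks = stats.rankdata(expr[pos], method="average")
            a[pos] = ranks / pos.sum()
        act[tissue] = a
    return pd.DataFrame(act, index=universe.expression.index)


@dataclass
class OccupancyModel:
    """Promoter nucleosome-depletion model for fragment sampling.

    ``depletion_depth`` in [0, 1] is the fractional dip of fragment
    intensity at a fully active promoter; ``depletion_width`` is the full
    width (2 sigma) of the inverted-Gaussian dip.  ``activity`` may supply
    an explicit transcripts × {placenta, blood} table in [0, 1]; when None
    it is derived from the universe's expression ranks.
    """

    baseline_depth: float = 1.0
    depletion_depth: float = 0.6
    depletion_width: float = 1000.0
    activity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.depletion_depth <= 1.0:
            raise ValueError("depletion_depth must lie in [0, 1]")
        if self.depletion_width <= 0:
            raise ValueError("depletion_width must be positive")
        if self.baseline_depth <= 0:
            raise ValueError("baseline_depth must be positive")
        if self.activity is not None:
            arr = self.activity[list(_TISSUES)].to_numpy(dtype=float)
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("activity values must lie in [0, 1]")

    @property
    def sigma(self) -> float:
        return self.depletion_width / 2.0


@dataclass
class CohortSpec:
    """Case/control cohort parameters.

    ``effect_lfc`` is the target log2 change of mean pTSS window coverage
    in cases at the planted promoters; 0 disables planting.  BMI is drawn
    Normal per group with the case mean shifted by ``bmi_case_shift``
    kg/m^2 (clinical direction: cases heavier); gestational age at
    sampling is matched between groups.
    """

    n_cases: int = 40
    n_controls: int = 40
    placental_fraction: float = 0.10
    planted_promoters: tuple[str, ...] = ()
    effect_lfc: float = 0.0
    fragments_per_sample: int = 150_000
    fragment_length_mean: float = 167.0
    fragment_length_sd: float = 20.0
    fragment_length_bounds: tuple[float, float] = (50.0, 400.0)
    bmi_mean: float = 21.3
    bmi_sd: float = 2.2
    bmi_case_shift: float = 1.5
    gestational_age_mean: float = 17.0
    gestational_age_sd: float = 3.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.placental_fraction <= 1.0:
            raise ValueError("placental_fraction must lie in [0, 1]")
        if self.fragments_per_sample <= 0:
            raise ValueError("fragments_per_sample must be positive")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be nonnegative")


def simulate_gene_universe(
    n_genes: int, n_chromosomes: int = 2, seed: int = 0
) -> GeneUniverse:
    """Random gene annotation plus two-tissue expression profiles.

    TSSs are spaced >= 10 kb apart so pTSS windows never overlap; both
    strands are represented.  Expression is long-tailed (log-normal) with
    a shared cross-tissue component, plus small placenta-specific,
    blood-specific, and unexpressed gene classes; named gene sets
    (top500/bottom500 by placental expression, tissue-specific,
    unexpressed) are populated.  Deterministic for a fixed seed.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_of = np.arange(n_genes) % n_chromosomes
    tss = np.zeros(n_genes, dtype=np.int64)
    chrom_sizes: dict[str, int] = {}
    for c in range(n_chromosomes):
        idx = np.where(chrom_of == c)[0]
        gaps = 10_000 + rng.integers(0, 5001, size=len(idx))
        tss[idx] = _EDGE_MARGIN + np.cumsum(gaps) - gaps[0]
        chrom_sizes[f"chr{c + 1}"] = int(tss[idx].max() + _EDGE_MARGIN)
    strand = rng.choice(["+", "-"], size=n_genes)

    # gene classes: ~5% each of unexpressed / placenta-specific / blood-specific
    order = rng.permutation(n_genes)
    n_special = max(1, round(0.05 * n_genes))
    unexpressed_idx = order[:n_special]
    pspec_idx = order[n_special : 2 * n_special]
    bspec_idx = order[2 * n_special : 3 * n_special]

    log_base = rng.normal(1.0, 1.2, size=n_genes)
    placenta = np.exp(log_base + rng.normal(0.0, 0.4, size=n_genes))
    blood = np.exp(log_base + rng.normal(0.0, 0.4, size=n_genes))
    placenta[unexpressed_idx] = 0.0
    blood[unexpressed_idx] = 0.0
    blood[pspec_idx] = 0.0
    placenta[bspec_idx] = 0.0

    width = len(str(n_genes))
    tids = [f"T{i + 1:0{width}d}" for i in range(n_genes)]
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    tx_start = np.where(strand == "+", tss, tss - _TX_BODY)
    tx_end = np.where(strand == "+", tss + _TX_BODY, tss)
    transcripts = pd.DataFrame(
        {
            "transcript_id": tids,
            "gene_symbol": genes,
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "strand": strand,
            "tss": tss,
            "tx_start": tx_start,
            "tx_end": tx_end,
        }
    )
    expression = pd.DataFrame(
        {"placenta": placenta, "blood": blood}, index=pd.Index(tids, name="transcript_id")
    )

    k = min(500, n_genes // 2)
    by_placenta = np.argsort(-placenta, kind="stable")
    gene_sets = {
        "top500": [tids[i] for i in by_placenta[:k]],
        "bottom500": [tids[i] for i in by_placenta[-k:]],
        "placenta_specific": [tids[i] for i in sorted(pspec_idx)],
        "blood_specific": [tids[i] for i in sorted(bspec_idx)],
        "unexpressed": [tids[i] for i in sorted(unexpressed_idx)],
    }
    return GeneUniverse(transcripts, expression, gene_sets, chrom_sizes)


class _Genome:
    """Precomputed lookup tables for fragment sampling."""

    def __init__(self, universe: GeneUniverse, occupancy: OccupancyModel):
        self.chroms = sorted(universe.chrom_sizes)
        self.sizes = np.array([universe.chrom_sizes[c] for c in self.chroms], dtype=float)
        self.cum = np.concatenate([[0.0], np.cumsum(self.sizes)])
        self.total = float(self.cum[-1])
        activity = occupancy.activity
        if activity is None:
            activity = activity_from_expression(universe)
        activity = activity.loc[universe.transcripts["transcript_id"]]
        self.tss_by_chrom: dict[int, np.ndarray] = {}
        self.act_by_chrom: dict[int, dict[str, np.ndarray]] = {}
        tx = universe.transcripts
        for ci, chrom in enumerate(self.chroms):
            mask = (tx["chrom"] == chrom).to_numpy()
            t = tx.loc[mask, "tss"].to_numpy(dtype=float)
            order = np.argsort(t)
            self.tss_by_chrom[ci] = t[order]
            self.act_by_chrom[ci] = {
                tissue: activity.loc[mask, tissue].to_numpy(dtype=float)[order]
                for tissue in _TISSUES
            }
        self.activity = activity

    def dip_fraction(self, chrom_idx: np.ndarray, pos: np.ndarray,
                     placental: np.ndarray, occupancy: OccupancyModel) -> np.ndarray:
        """a * d * K(pos - nearest TSS); zero beyond 4 sigma."""
        sigma = occupancy.sigma
        out = np.zeros(len(pos))
        for ci in np.unique(chrom_idx):
            m = chrom_idx == ci
            t = self.tss_by_chrom[ci]
            if len(t) == 0:
                continue
            p = pos[m]
            j = np.searchsorted(t, p)
            left = np.clip(j - 1, 0, len(t) - 1)
            right = np.clip(j, 0, len(t) - 1)
            d_left = np.abs(p - t[left])
            d_right = np.abs(p - t[right])
            nearest = np.where(d_left <= d_right, left, right)
            dist = np.minimum(d_left, d_right)
            a_pl = self.act_by_chrom[ci]["placenta"][nearest]
            a_bl = self.act_by_chrom[ci]["blood"][nearest]
            a = np.where(placental[m], a_pl, a_bl)
            kernel = np.where(
                dist <= 4.0 * sigma, np.exp(-(dist**2) / (2.0 * sigma**2)), 0.0
            )
            out[m] = a * occupancy.depletion_depth * kernel
        return out


def _sample_lengths(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    lo, hi = spec.fragment_length_bounds
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(spec.fragment_length_mean, spec.fragment_length_sd, n - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return np.round(out).astype(np.int64)


def _fragmentset_from_arrays(
    sample_id: str, chroms: list[str], chrom_idx: np.ndarray,
    starts: np.ndarray, ends: np.ndarray,
) -> FragmentSet:
    by_chrom = {}
    for ci in np.unique(chrom_idx):
        m = chrom_idx == ci
        s = starts[m]
        e = ends[m]
        order = np.argsort(s, kind="stable")
        by_chrom[chroms[ci]] = (s[order], e[order], np.sort(e), int((e - s).max()))
    return FragmentSet(sample_id=sample_id, _by_chrom=by_chrom, total_mapped=len(starts))


def simulate_sample_fragments(
    universe: GeneUniverse,
    occupancy: OccupancyModel,
    spec: CohortSpec,
    is_case: bool,
    sample_seed: int,
    sample_id: str | None = None,
    _genome: "_Genome | None" = None,
) -> FragmentSet:
    """Draw one sample's fragments from the two-tissue footprint model.

    Fragment midpoints are proposed uniformly on the genome (plus, for
    case samples with planted promoters, an extra uniform component over
    the planted pTSS windows carrying mass ``(2**effect_lfc - 1)`` per bp)
    and accepted with probability ``1 - activity*depletion_depth*K`` where
    K is the Gaussian dip kernel of the nearest promoter in the fragment's
    tissue of origin.  Exactly ``fragments_per_sample`` fragments are
    returned; deterministic per ``sample_seed``.
    """
    genome = _genome or _Genome(universe, occupancy)
    rng = np.random.default_rng(sample_seed)
    n_target = spec.fragments_per_sample

    planted: list[str] = []
    if is_case and spec.effect_lfc != 0.0 and spec.planted_promoters:
        planted = list(spec.planted_promoters)
    boost = 2.0 ** spec.effect_lfc
    half = _PTSS_FLANK + spec.fragment_length_mean / 2.0
    if planted:
        tx = universe.transcripts.set_index("transcript_id")
        p_chrom = np.array(
            [genome.chroms.index(tx.loc[t, "chrom"]) for t in planted], dtype=np.int64
        )
        p_tss = tx.loc[planted, "tss"].to_numpy(dtype=float)
        mass_extra = (boost - 1.0) * 2.0 * half * len(planted)
    else:
        mass_extra = 0.0
    q_extra = mass_extra / (genome.total + mass_extra)

    got_chrom: list[np.ndarray] = []
    got_mid: list[np.ndarray] = []
    n_have = 0
    while n_have < n_target:
        batch = int((n_target - n_have) / 0.85) + 64
        placental = rng.random(batch) < spec.placental_fraction
        from_extra = rng.random(batch) < q_extra
        glob = rng.random(batch) * genome.total
        chrom_idx = np.searchsorted(genome.cum, glob, side="right") - 1
        pos = glob - genome.cum[chrom_idx]
        if planted:
            n_b = int(from_extra.sum())
            which = rng.integers(0, len(planted), size=n_b)
            pos_b = p_tss[which] - half + rng.random(n_b) * 2.0 * half
            chrom_idx[from_extra] = p_chrom[which]
            pos[from_extra] = pos_b
        dip = genome.dip_fraction(chrom_idx, pos, placental, occupancy)
        accept = rng.random(batch) >= dip
        got_chrom.append(chrom_idx[accept])
        got_mid.append(pos[accept])
        n_have += int(accept.sum())
    chrom_idx = np.concatenate(got_chrom)[:n_target]
    mid = np.concatenate(got_mid)[:n_target]
    lengths = _sample_lengths(rng, n_target, spec)
    starts = np.maximum(0, np.round(mid - lengths / 2.0).astype(np.int64))
    ends = starts + lengths
    sizes = genome.sizes[chrom_idx].astype(np.int64)
    over = ends > sizes
    if over.any():
        ends[over] = sizes[over]
        starts[over] = np.minimum(starts[over], ends[over] - 1)
    return _fragmentset_from_arrays(
        sample_id or f"sample_{sample_seed}", genome.chroms, chrom_idx, starts, ends
    )


def _sample_seed(master: int, index: int) -> int:
    # fixed integer offsets from the master seed, kept below 2**31
    return int((master + 10_007 * (index + 1)) % (2**31))


def simulate_cohort(
    universe: GeneUniverse,
    occupancy: OccupancyModel,
    spec: CohortSpec,
    cohort_name: str = "training",
) -> tuple[list[FragmentSet], pd.DataFrame, dict]:
    """Simulate a case/control cohort with optional planted promoters.

    Returns the per-sample fragment sets, a metadata table (sample_id,
    cohort, label, bmi, gestational_age), and a truth record listing the
    planted promoters and generative parameters.  ``effect_lfc = 0``
    yields a null cohort (cases and controls identical in law; the planted
    set is recorded as empty).
    """
    known = set(universe.transcripts["transcript_id"])
    missing = set(spec.planted_promoters) - known
    if missing:
        raise ValueError(f"planted promoter(s) absent from universe: {sorted(missing)}")
    genome = _Genome(universe, occupancy)
    samples: list[FragmentSet] = []
    records = []
    rng_meta = np.random.default_rng(_sample_seed(spec.seed, 0))
    index = 0
    for label, count in (("case", spec.n_cases), ("control", spec.n_controls)):
        for i in range(count):
            index += 1
            sid = f"{cohort_name}_{label}_{i + 1:03d}"
            fs = simulate_sample_fragments(
                universe,
                occupancy,
                spec,
                is_case=(label == "case"),
                sample_seed=_sample_seed(spec.seed, index),
                sample_id=sid,
                _genome=genome,
            )
            samples.append(fs)
            bmi_mu = spec.bmi_mean + (spec.bmi_case_shift if label == "case" else 0.0)
            records.append(
                {
                    "sample_id": sid,
                    "cohort": cohort_name,
                    "label": label,
                    "bmi": round(float(rng_meta.normal(bmi_mu, spec.bmi_sd)), 2),
                    "gestational_age": round(
                        float(
                            rng_meta.normal(
                                spec.gestational_age_mean, spec.gestational_age_sd
                            )
                        ),
                        1,
                    ),
                }
            )
    metadata = pd.DataFrame.from_records(records)
    planted = (
        list(spec.planted_promoters) if spec.effect_lfc != 0.0 else []
    )
    truth = {
        "cohort": cohort_name,
        "planted_promoters": planted,
        "effect_lfc": spec.effect_lfc if planted else 0.0,
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "placental_fraction": spec.placental_fraction,
        "fragments_per_sample": spec.fragments_per_sample,
        "depletion_depth": occupancy.depletion_depth,
        "depletion_width": occupancy.depletion_width,
        "seed": spec.seed,
    }
    return samples, metadata, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixtures(
    universe: GeneUniverse,
    samples: Sequence[FragmentSet],
    metadata: pd.DataFrame,
    truth: Mapping | None,
    directory: str | Path,
) -> dict:
    """Write a cohort as plain-text fixtures and return a checksum manifest.

    Fragments go to one BED3 file per sample, the annotation to a
    refFlat-style TSV, metadata to TSV, and the truth record to JSON; the
    manifest (also written as ``manifest.json``) maps each file to its
    SHA-256 checksum.  Re-running with the same inputs reproduces the
    files byte-for-byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    ann_path = directory / "annotation.refflat.tsv"
    with open(ann_path, "w") as handle:
        for row in universe.transcripts.itertuples(index=False):
            handle.write(
                f"{row.gene_symbol}\t{row.transcript_id}\t{row.chrom}\t"
                f"{row.strand}\t{row.tx_start}\t{row.tx_end}\n"
            )
    files["annotation.refflat.tsv"] = _sha256(ann_path)

    meta_path = directory / "metadata.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False)
    files["metadata.tsv"] = _sha256(meta_path)

    if truth is not None:
        truth_path = directory / "truth.json"
        truth_path.write_text(json.dumps(dict(truth), indent=2, sort_keys=True) + "\n")
        files["truth.json"] = _sha256(truth_path)

    for fs in samples:
        bed_path = directory / f"{fs.sample_id}.bed"
        with open(bed_path, "w") as handle:
            for chrom, start, end in fs.fragments():
                handle.write(f"{chrom}\t{start}\t{end}\n")
        files[bed_path.name] = _sha256(bed_path)

    manifest = {"files": files, "n_samples": len(samples)}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
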