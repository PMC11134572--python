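"""Synthetic inputs for the full pipeline: matrices, proteins with planted
epitopes and Tregitopes, population frequency tables, and paired scores.

Matrix entries are independent standard Gaussians.  This choice makes the
raw-score null for a random 9-mer a sum of nine independent terms whose
marginal (over matrices) is exactly normal, so the analytic Z-calibration
and the e0 hit-excess constant are exact in expectation and the ~5% hit
rate at Z >= 1.64 is provable rather than approximate.

Protein planting is constructive: planted frames are built greedily from the
target allele's best residues (falling back to sampling among the top
residues per position when the pure argmax leaks an off-target hit at the
planted frame), and all remaining frames are repaired by resampling free
residues until nothing outside the plants reaches the "likely" tier.  The
generator returns exact ground truth, so scanning tests can demand zero
misses and zero false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .frequencies import FrequencyTable
from .pssm import (
    NINE,
    AminoAlphabet,
    BackgroundFrequencies,
    HitThresholds,
    PSSM,
    null_moments,
)
from .scanning import ProteinRecord, TregitopeRegistry, frame_scores
from .stats import PairedSamples


class GenerationError(RuntimeError):
    """Planting constraints could not be satisfied within bounded retries."""


@dataclass
class PlantedEpitope:
    """A strong-binder 9-mer to embed: (allele, 1-based frame start, target Z)."""

    allele: str
    position: int
    target_z: float = 2.0


@dataclass
class PlantedTregitope:
    """A registry peptide carved out of the final sequence at a fixed span."""

    registry_id: str
    position: int  # 1-based start
    length: int = 15


@dataclass
class PopulationSpec:
    """Target carrier fractions and aggregated sample size for one population."""

    label: str
    total_n: int
    carrier: dict[str, float]


@dataclass
class SimSpec:
    """Everything needed to generate one synthetic dataset."""

    seed: int = 0
    n_alleles: int = 8
    protein_length: int = 300
    epitopes: list[PlantedEpitope] = field(default_factory=list)
    tregitopes: list[PlantedTregitope] = field(default_factory=list)
    populations: list[PopulationSpec] = field(default_factory=list)
    shift: float = 0.0

    def __post_init__(self) -> None:
        for e in self.epitopes:
            if not 1 <= e.position <= self.protein_length - NINE + 1:
                raise GenerationError(f"planted epitope at {e.position} out of bounds")
        for t in self.tregitopes:
            if not 1 <= t.position <= self.protein_length - t.length + 1:
                raise GenerationError(f"planted tregitope at {t.position} out of bounds")
        for p in self.populations:
            for allele, frac in p.carrier.items():
                if not 0.0 <= frac <= 1.0:
                    raise GenerationError(
                        f"carrier fraction {frac} for {allele} outside [0, 1]"
                    )


def synthetic_allele_names(n: int) -> list[str]:
    """Plausible-looking two-field DRB1 names for synthetic matrices."""
    return [f"DRB1*{80 + i // 10}:{i % 10 + 1:02d}" for i in range(n)]


def generate_pssm_set(
    n_alleles: int, seed: int, alphabet: AminoAlphabet | None = None
) -> list[PSSM]:
    """Independent standard-Gaussian 9x20 matrices, one per synthetic allele."""
    if n_alleles < 1:
        raise GenerationError("n_alleles must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    alphabet = alphabet or AminoAlphabet()
    return [
        PSSM(
            allele=name,
            matrix=rng.standard_normal((NINE, 20)),
            source_tag=f"synthetic seed={seed}",
            alphabet=alphabet,
        )
        for name in synthetic_allele_names(n_alleles)
    ]


def _z_grid(
    encoded: np.ndarray, pssms: Sequence[PSSM], moments
) -> np.ndarray:
    n_frames = len(encoded) - NINE + 1
    z = np.empty((n_frames, len(pssms)))
    for j, (pssm, nm) in enumerate(zip(pssms, moments)):
        z[:, j] = (frame_scores(encoded, pssm.matrix) - nm.mu) / nm.sigma
    return z


def _plant_frame(
    rng: np.random.Generator,
    matrix: np.ndarray,
    off_matrices: list[np.ndarray],
    nm,
    off_nms,
    target_z: float,
    likely: float,
    max_tries: int = 1000,
    top_m: int = 5,
    greedy_first: bool = True,
) -> np.ndarray:
    """Choose nine residues scoring Z >= target for the target allele while
    every off-target allele stays below the likely tier on that frame."""
    order = np.argsort(-matrix, axis=1)  # residues by descending score per position
    for attempt in range(max_tries):
        if attempt == 0 and greedy_first:
            choice = order[:, 0]  # pure greedy argmax first
        else:
            choice = order[np.arange(NINE), rng.integers(0, top_m, size=NINE)]
        raw = matrix[np.arange(NINE), choice].sum()
        if (raw - nm.mu) / nm.sigma < target_z:
            continue
        ok = True
        for om, onm in zip(off_matrices, off_nms):
            oraw = om[np.arange(NINE), choice].sum()
            if (oraw - onm.mu) / onm.sigma >= likely:
                ok = False
                break
        if ok:
            return choice
    raise GenerationError(
        "could not satisfy planted-frame constraints within bounded retries"
    )


def _repair(
    encoded: np.ndarray,
    pssms: Sequence[PSSM],
    moments,
    plant_cells: set[tuple[int, int]],
    protected: np.ndarray,
    likely: float,
    max_repair: int,
    rng: np.random.Generator | None = None,
    noise: float = 0.2,
) -> bool:
    """Greedy descent: lower every non-planted cell below the likely tier.

    Each step takes the worst violating cell and applies the single free
    residue change that minimizes the worst Z over the frames it touches
    (a residue change only affects the nine frames covering it, so the
    global max never rises).  The Z grid is maintained incrementally and
    all 20 candidate residues per free position are evaluated at once.
    With probability ``noise`` — and always when no strictly improving move
    exists — a random violating frame takes its least-bad residue change
    even if the penalty rises (the WalkSAT escape for tightly coupled
    near-threshold frames).  Returns False when the iteration budget runs
    out or a violating frame has no free residues; callers then regenerate
    from scratch.
    """
    rng = rng or np.random.default_rng(0)
    n_frames = len(encoded) - NINE + 1
    n_k = len(pssms)
    mats = np.stack([p.matrix for p in pssms])  # (K, 9, 20)
    mu = np.array([nm.mu for nm in moments])
    sigma = np.array([nm.sigma for nm in moments])
    plant_mask = np.zeros((n_frames, n_k), dtype=bool)
    for a, f1 in plant_cells:
        plant_mask[f1 - 1, a] = True

    def z_rows(lo: int, hi: int) -> np.ndarray:
        out = np.zeros((hi - lo + 1, n_k))
        for k in range(NINE):
            out += mats[:, k, encoded[lo + k : hi + k + 1]].T
        return (out - mu) / sigma

    z = z_rows(0, n_frames - 1)
    # squared-hinge penalty above a margin just below the likely tier; a
    # move may trade one near-threshold cell against another as long as the
    # total window penalty strictly decreases, so the global penalty is a
    # monotone Lyapunov function of the search
    thr = likely - 0.01

    def window_penalty(zw: np.ndarray, mask: np.ndarray) -> float:
        excess = np.where(mask, 0.0, np.maximum(zw - thr, 0.0))
        return float((excess**2).sum())

    frame_has_free = np.array(
        [not protected[f : f + NINE].all() for f in range(n_frames)]
    )

    def best_move(f: int) -> tuple[float, int, int, int, int] | None:
        """Largest-gain single-residue change among frame f's free positions."""
        best: tuple[float, int, int, int, int] | None = None
        for pos in range(f, f + NINE):
            if protected[pos]:
                continue
            lo = max(0, pos - NINE + 1)
            hi = min(n_frames - 1, pos)
            fr = np.arange(lo, hi + 1)
            kpos = pos - fr  # matrix position index of pos in each frame
            cur = int(encoded[pos])
            # candidate z for all 20 residues: (res, frame, allele)
            delta = (
                mats[:, kpos, :].transpose(2, 1, 0) - mats[:, kpos, cur].T
            ) / sigma
            cand = z[fr][None, :, :] + delta
            excess = np.where(
                plant_mask[fr][None, :, :], 0.0, np.maximum(cand - thr, 0.0)
            )
            pen = (excess**2).sum(axis=(1, 2))
            pen[cur] = np.inf  # a no-op change can never be the repair
            res = int(np.argmin(pen))
            gain = window_penalty(z[fr], plant_mask[fr]) - float(pen[res])
            if best is None or gain > best[0]:
                best = (gain, pos, res, lo, hi)
        return best

    for _ in range(max_repair):
        viol = (z >= likely) & ~plant_mask
        if not viol.any():
            return True
        move = None
        if rng.random() >= noise:
            # greedy: worst cells first, take the first strict improvement
            zv = np.where(viol, z, -np.inf)
            order = np.argsort(zv, axis=None)[::-1]
            for flat in order[: min(20, int(viol.sum()))]:
                f, a = np.unravel_index(flat, z.shape)
                if not viol[f, a]:
                    break
                candidate = best_move(int(f))
                if candidate is not None and candidate[0] > 1e-12:
                    move = candidate
                    break
        if move is None:
            # noise step: least-bad move in a random repairable violating frame
            vf = [int(f) for f in np.unique(np.where(viol)[0]) if frame_has_free[f]]
            if not vf:
                return False
            move = best_move(int(rng.choice(vf)))
            if move is None:
                return False
        _, pos, res, lo, hi = move
        encoded[pos] = res
        z[lo : hi + 1] = z_rows(lo, hi)
    return False


def plant_protein(
    spec: SimSpec,
    matrices: Sequence[PSSM],
    bg: BackgroundFrequencies | None = None,
    thresholds: HitThresholds | None = None,
    max_repair: int = 5000,
    protein_id: str = "synthetic",
) -> tuple[ProteinRecord, dict, TregitopeRegistry]:
    """Generate a protein with exactly the planted epitope/Tregitope content.

    Returns the protein, a ground-truth dict with ``hits`` (list of
    (allele, frame) pairs) and ``tregitope_spans`` (1-based inclusive), and a
    registry whose peptides are the exact planted subsequences.  Every
    non-planted (frame, allele) cell scores below the likely tier by
    construction; unsatisfiable specs raise :class:`GenerationError`.
    """
    pssms = sorted(matrices, key=lambda p: p.allele)
    alphabet = pssms[0].alphabet
    bg = bg or BackgroundFrequencies.uniform(alphabet)
    t = thresholds or HitThresholds()
    by_allele = {p.allele: i for i, p in enumerate(pssms)}
    moments = [null_moments(p, bg) for p in pssms]
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    p_bg = bg.as_array(alphabet)
    length = spec.protein_length

    # planted epitope spans must not overlap each other
    plant_cells = set()
    protected = np.zeros(length, dtype=bool)
    for e in spec.epitopes:
        if e.allele not in by_allele:
            raise GenerationError(f"planted allele {e.allele} has no matrix")
        span = slice(e.position - 1, e.position - 1 + NINE)
        if protected[span].any():
            raise GenerationError("planted epitopes overlap")
        protected[span] = True
        plant_cells.add((by_allele[e.allele], e.position))

    for outer in range(50):
        encoded = rng.choice(20, size=length, p=p_bg)
        for e in spec.epitopes:
            j = by_allele[e.allele]
            off = [i for i in range(len(pssms)) if i != j]
            encoded[e.position - 1 : e.position - 1 + NINE] = _plant_frame(
                rng,
                pssms[j].matrix,
                [pssms[i].matrix for i in off],
                moments[j],
                [moments[i] for i in off],
                e.target_z,
                t.likely,
                greedy_first=(outer == 0),
            )
        # local repair: knock down any non-planted cell at/above the likely tier
        if not _repair(
            encoded, pssms, moments, plant_cells, protected, t.likely, max_repair, rng
        ):
            continue
        # verify planted frames meet their targets after repair
        z = _z_grid(encoded, pssms, moments)
        if all(
            z[e.position - 1, by_allele[e.allele]] >= e.target_z
            for e in spec.epitopes
        ):
            break
    else:
        raise GenerationError("protein generation failed after bounded retries")

    sequence = "".join(alphabet.residues[i] for i in encoded)
    protein = ProteinRecord(id=protein_id, sequence=sequence)

    # registry peptides are the exact planted subsequences, so matching is
    # guaranteed and planted epitopes inside a Tregitope span stay intact
    entries = []
    spans = []
    for treg in spec.tregitopes:
        s, e_ = treg.position, treg.position + treg.length - 1
        entries.append((treg.registry_id, sequence[s - 1 : e_]))
        spans.append((s, e_))
    registry = TregitopeRegistry(entries=entries)

    truth = {
        "hits": sorted((e.allele, e.position) for e in spec.epitopes),
        "tregitope_spans": sorted(spans),
    }
    return protein, truth, registry


def generate_random_proteins(
    n: int,
    length: int,
    seed: int,
    bg: BackgroundFrequencies | None = None,
    alphabet: AminoAlphabet | None = None,
    id_prefix: str = "random",
) -> list[ProteinRecord]:
    """Unconstrained background-random proteins (the null ensemble)."""
    alphabet = alphabet or AminoAlphabet()
    bg = bg or BackgroundFrequencies.uniform(alphabet)
    p_bg = bg.as_array(alphabet)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    out = []
    for i in range(n):
        encoded = rng.choice(20, size=length, p=p_bg)
        out.append(
            ProteinRecord(
                id=f"{id_prefix}_{i}",
                sequence="".join(alphabet.residues[j] for j in encoded),
            )
        )
    return out


def generate_population_tables(
    spec: SimSpec, noise: bool = False
) -> list[FrequencyTable]:
    """Frequency tables with exactly the requested carrier fractions.

    With ``noise=True`` the observed fractions are drawn binomially at each
    population's sample size instead (seeded from the spec).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    tables = []
    for pop in spec.populations:
        carrier = dict(pop.carrier)
        if noise:
            carrier = {
                a: float(rng.binomial(pop.total_n, f)) / pop.total_n
                for a, f in carrier.items()
            }
        tables.append(
            FrequencyTable(population=pop.label, carrier=carrier, total_n=pop.total_n)
        )
    return tables


def simulate_dataset(config: dict, out_dir) -> dict:
    """Generate a complete on-disk dataset from a simulation config.

    Config keys: ``seed``, ``n_alleles``, ``populations`` (label, total_n,
    optional default_carrier applied to every matrix allele, optional
    carrier overrides) and ``proteins`` (id, length, planted epitopes and
    tregitopes).  Writes matrix CSVs, a protein FASTA, a Tregitope registry
    FASTA, an aggregated frequency CSV and a ground-truth JSON in the same
    dialects the analysis pipeline consumes; returns the written paths.
    """
    import json
    from pathlib import Path

    from .frequencies import write_frequency_csv
    from .io import write_proteins_fasta, write_registry_fasta
    from .pssm import write_pssm_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_alleles = int(config.get("n_alleles", 8))
    pssms = generate_pssm_set(n_alleles, seed)
    alleles = [p.allele for p in pssms]

    matrix_dir = out / "matrices"
    matrix_dir.mkdir(exist_ok=True)
    for p in pssms:
        safe = p.allele.replace("*", "_").replace(":", "")
        write_pssm_csv(p, matrix_dir / f"{safe}.csv")

    proteins = []
    entries: list[tuple[str, str]] = []
    truth = {}
    for i, pconf in enumerate(config.get("proteins", [])):
        spec = SimSpec(
            seed=seed + 1000 * (i + 1),
            n_alleles=n_alleles,
            protein_length=int(pconf.get("length", 300)),
            epitopes=[
                PlantedEpitope(
                    allele=e["allele"],
                    position=int(e["position"]),
                    target_z=float(e.get("target_z", 2.0)),
                )
                for e in pconf.get("epitopes", [])
            ],
            tregitopes=[
                PlantedTregitope(
                    registry_id=t["id"],
                    position=int(t["position"]),
                    length=int(t.get("length", 15)),
                )
                for t in pconf.get("tregitopes", [])
            ],
        )
        protein, ptruth, registry = plant_protein(
            spec, pssms, protein_id=pconf["id"]
        )
        proteins.append(protein)
        entries.extend(registry.entries)
        truth[protein.id] = ptruth

    tables = []
    for pop in config.get("populations", []):
        default = float(pop.get("default_carrier", 0.1))
        carrier = {a: default for a in alleles}
        carrier.update({a: float(v) for a, v in (pop.get("carrier") or {}).items()})
        tables.append(
            FrequencyTable(
                population=pop["label"],
                carrier=carrier,
                total_n=int(pop.get("total_n", 5000)),
            )
        )

    paths = {
        "matrix_dir": str(matrix_dir),
        "proteins": str(out / "proteins.fasta"),
        "registry": str(out / "tregitopes.fasta"),
        "frequencies": str(out / "frequencies.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_proteins_fasta(proteins, paths["proteins"])
    write_registry_fasta(TregitopeRegistry(entries=entries), paths["registry"])
    write_frequency_csv(tables, paths["frequencies"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def generate_paired_scores(n: int, shift: float, seed: int) -> PairedSamples:
    """Index-paired score samples with a planted location shift.

    Pairs share a common component (as resample pairs built from common
    random substreams do); differences are N(shift, 1).
    """
    if n < 1:
        raise GenerationError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    base = rng.normal(0.0, 1.0, size=n)
    x = base + rng.normal(0.0, 0.5, size=n)
    y = base + shift + np.sqrt(1.0 - 0.25) * rng.normal(0.0, 1.0, size=n)
    return PairedSamples(label=f"shift={shift:g}", x=x, y=y)
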