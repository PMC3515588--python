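"""Pseudo-observed dataset generation and file plumbing.

Writers/readers for Genepop (2- and 3-digit) and FASTA, the seeded
pseudo-observed bundle emulating the study design (1 native + 3 introduced
sampled populations, 5 microsatellite loci, 600 bp + 400 bp mtDNA
fragments), and the end-to-end pipeline driver.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from invaroute import abc as abcmod
from invaroute import neutrality, popstats
from invaroute.coalsim import FRAGMENT_LENGTHS, SampleConfig, SimDataset, simulate_dataset
from invaroute.demography import (
    ParameterDraw,
    Scenario,
    build_builtin_scenario,
    prior_support,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoObservedBundle",
    "make_pseudo_observed",
    "read_genepop",
    "write_genepop",
    "read_fasta",
    "write_fasta",
    "dataset_to_files",
    "dataset_from_files",
    "run_pipeline",
    "DEFAULT_TRUTH",
]

#: allele scores are repeat displacements around 0; offset keeps codes positive
GENEPOP_ALLELE_OFFSET = 100

DEFAULT_TRUTH = {
    "t1": 75.0,
    "t2": 100.0,
    "t3": 200.0,
    "r": 0.5,
    "micro_mean_mu": 5e-4,
    "mt_mu": 1e-6,
}


# ---------------------------------------------------------------------------
# Genepop


def write_genepop(
    data: dict[str, np.ndarray],
    path,
    title: str = "invaroute microsatellite data",
    digits: int = 3,
    offset: int = GENEPOP_ALLELE_OFFSET,
) -> None:
    """Write a dict of population -> (n, L, 2) allele-score arrays.

    Scores are written as ``score + offset`` with ``digits`` digits per
    allele; individuals are labelled ``pop_i``.
    """
    pops = list(data)
    n_loci = data[pops[0]].shape[1]
    lines = [title]
    lines += [f"locus{l + 1}" for l in range(n_loci)]
    limit = 10**digits
    for pop in pops:
        lines.append("Pop")
        geno = data[pop]
        for i in range(geno.shape[0]):
            codes = []
            for l in range(n_loci):
                a, b = geno[i, l]
                if not (0 < a + offset < limit and 0 < b + offset < limit):
                    raise ValueError(
                        f"allele score out of Genepop code range at {pop}_{i + 1}"
                    )
                codes.append(f"{a + offset:0{digits}d}{b + offset:0{digits}d}")
            lines.append(f"{pop}_{i + 1} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(
    path,
    offset: int = GENEPOP_ALLELE_OFFSET,
    drop_missing: bool = True,
):
    """Parse a 2- or 3-digit Genepop file.

    Returns ``(data, pop_names, flagged)`` where ``data`` maps population
    name -> (n, L, 2) int array of allele scores (``code - offset``),
    ``pop_names`` preserves file order and ``flagged`` lists individual
    labels that carried a missing genotype (code 0).  Missing individuals
    are dropped when ``drop_missing`` is set.
    """
    text = Path(path).read_text().strip().splitlines()
    if not text:
        raise ValueError("empty Genepop file")
    lines = [ln.rstrip() for ln in text]
    # locus names: one per line (or one comma-separated line) until first Pop
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if "," in part:
            loci += [x.strip() for x in part.split(",") if x.strip()]
        elif part:
            loci.append(part)
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' separator found")
    n_loci = len(loci)

    digit_width: int | None = None
    pops: list[str] = []
    raw: list[list[tuple[str, np.ndarray, bool]]] = []
    current: list[tuple[str, np.ndarray, bool]] | None = None
    for ln in lines[i:]:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            current = []
            raw.append(current)
            continue
        if current is None:
            raise ValueError("genotype line before first 'Pop'")
        if "," not in stripped:
            raise ValueError(f"malformed individual line (no comma): {stripped!r}")
        label, genostr = stripped.split(",", 1)
        label = label.strip()
        codes = genostr.split()
        if len(codes) != n_loci:
            raise ValueError(
                f"individual {label!r}: {len(codes)} genotypes for {n_loci} loci"
            )
        geno = np.empty((n_loci, 2), dtype=np.int64)
        missing = False
        for l, code in enumerate(codes):
            if not code.isdigit() or len(code) not in (4, 6):
                raise ValueError(f"malformed genotype {code!r} for {label!r}")
            w = len(code) // 2
            if digit_width is None:
                digit_width = w
            elif w != digit_width:
                raise ValueError("inconsistent digit width within file")
            a, b = int(code[:w]), int(code[w:])
            if a == 0 or b == 0:
                missing = True
            geno[l] = (a - offset, b - offset)
        current.append((label, geno, missing))
    data: dict[str, np.ndarray] = {}
    flagged: list[str] = []
    for block in raw:
        if not block:
            continue
        name = block[0][0].rsplit("_", 1)[0] if "_" in block[0][0] else block[0][0]
        keep = []
        for label, geno, missing in block:
            if missing:
                flagged.append(label)
                if drop_missing:
                    continue
            keep.append(geno)
        data[name] = (
            np.stack(keep, axis=0) if keep else np.empty((0, n_loci, 2), dtype=np.int64)
        )
        pops.append(name)
    return data, pops, flagged


# ---------------------------------------------------------------------------
# FASTA

_BASES = np.frombuffer(b"ACGTN", dtype="S1")


def _codes_to_str(row: np.ndarray) -> str:
    return _BASES[np.minimum(row, 4)].tobytes().decode()


def write_fasta(alignment: dict[str, np.ndarray], path) -> None:
    """Write per-population base-index arrays; IDs are ``pop_i``."""
    records = []
    for pop, arr in alignment.items():
        for i in range(arr.shape[0]):
            records.append(
                SeqRecord(Seq(_codes_to_str(arr[i])), id=f"{pop}_{i + 1}",
                          description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, require_alignment: bool = True):
    """Read a FASTA file into ``(ids, (n, L) uint8 array)``.

    Sequences are upper-cased; non-ACGT symbols map to code 4.  Duplicate
    IDs and (when ``require_alignment``) unequal lengths are errors.
    """
    ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate sequence ID {rec.id!r}")
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence {rec.id!r}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError("no sequences found")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        if require_alignment:
            raise ValueError("sequences have unequal lengths")
        return ids, [popstats.as_base_array([s])[0] for s in seqs]
    return ids, popstats.as_base_array(seqs)


def _fasta_by_population(ids: list[str], arr: np.ndarray) -> dict[str, np.ndarray]:
    by_pop: dict[str, list[int]] = {}
    for i, sid in enumerate(ids):
        pop = sid.rsplit("_", 1)[0]
        by_pop.setdefault(pop, []).append(i)
    return {pop: arr[rows] for pop, rows in by_pop.items()}


# ---------------------------------------------------------------------------
# pseudo-observed bundle


@dataclass
class PseudoObservedBundle:
    """Files plus truth record for one seeded pseudo-observed dataset."""

    genepop_path: Path
    fasta_paths: dict[str, Path]
    truth_path: Path
    dataset: SimDataset
    truth: dict


def make_pseudo_observed(
    out_dir,
    rng_seed: int,
    scenario: Scenario | None = None,
    truth: dict | None = None,
    n_diploids: int = 30,
    n_sequences: int = 10,
) -> PseudoObservedBundle:
    """Simulate one dataset at known truth values and write it to disk as a
    Genepop file, one FASTA per fragment and a JSON truth record."""
    scenario = scenario or build_builtin_scenario("scenario1")
    truth = dict(DEFAULT_TRUTH, **(truth or {}))
    for name, value in truth.items():
        lo, hi = prior_support(scenario.prior(name))
        if not lo <= value <= hi:
            raise ValueError(
                f"truth {name}={value} outside prior support [{lo}, {hi}]"
            )
    cfg = SampleConfig.uniform(
        scenario.sampled_populations, n_diploids, n_sequences
    )
    draw = ParameterDraw(values=truth, seed=int(rng_seed))
    ds = simulate_dataset(scenario, draw, cfg, int(rng_seed))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genepop_path = out / "microsats.genepop.txt"
    write_genepop(ds.genotypes, genepop_path)
    fasta_paths = {}
    for frag in ds.fragment_names:
        p = out / f"{frag}.fasta"
        write_fasta(ds.sequences[frag], p)
        fasta_paths[frag] = p
    record = {
        "scenario": scenario.label,
        "seed": int(rng_seed),
        "truth": truth,
        "n_diploids": n_diploids,
        "n_sequences": n_sequences,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(record, indent=2) + "\n")
    return PseudoObservedBundle(genepop_path, fasta_paths, truth_path, ds, record)


def dataset_to_files(ds: SimDataset, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"genepop": out / "microsats.genepop.txt"}
    write_genepop(ds.genotypes, paths["genepop"])
    for frag in ds.fragment_names:
        paths[frag] = out / f"{frag}.fasta"
        write_fasta(ds.sequences[frag], paths[frag])
    return paths


def dataset_from_files(genepop_path, fasta_paths: dict[str, ...]) -> SimDataset:
    """Rebuild a :class:`SimDataset` from a Genepop file and per-fragment
    FASTA files."""
    genotypes, pops, _ = read_genepop(genepop_path)
    sequences: dict[str, dict[str, np.ndarray]] = {}
    for frag, path in fasta_paths.items():
        ids, arr = read_fasta(path)
        sequences[frag] = _fasta_by_population(ids, arr)
    return SimDataset(
        populations=sorted(pops),
        genotypes=genotypes,
        sequences=sequences,
        provenance={"genepop": str(genepop_path)},
    )


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG = {
    "seed": 1,
    "n_sims": 20_000,
    "tolerance": 0.01,
    "n_diploids": 30,
    "n_sequences": 10,
    "neutrality_reps": 1000,
    "scenarios": ["scenario1", "scenario2"],
    "pseudo_observed": {"scenario": "scenario1", "truth": {}},
    "observed": None,  # or {"genepop": path, "fragments": {name: path}}
}


def run_pipeline(config_path, out_dir=None) -> dict:
    """Run the full chain: observed (or pseudo-observed) data -> summary
    vector -> reference tables -> model choice -> parameter estimation on
    the winning scenario -> neutrality and mismatch per population ->
    diversity table.  Returns the report dict (also written to JSON)."""
    config_path = Path(config_path)
    cfg_in = yaml.safe_load(config_path.read_text()) or {}
    cfg = {**DEFAULT_CONFIG, **cfg_in}
    out = Path(out_dir) if out_dir else config_path.parent / "invaroute_out"
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    rng_root = np.random.SeedSequence(seed)
    stage_seeds = rng_root.generate_state(8, dtype=np.uint32)

    logger.info("stage: observed data")
    if cfg.get("observed"):
        obs_cfg = cfg["observed"]
        dataset = dataset_from_files(
            obs_cfg["genepop"], {k: Path(v) for k, v in obs_cfg["fragments"].items()}
        )
        truth = None
    else:
        po = cfg.get("pseudo_observed") or {}
        bundle = make_pseudo_observed(
            out / "pseudo_observed",
            int(stage_seeds[0]),
            scenario=build_builtin_scenario(po.get("scenario", "scenario1")),
            truth=po.get("truth") or None,
            n_diploids=int(cfg["n_diploids"]),
            n_sequences=int(cfg["n_sequences"]),
        )
        dataset = bundle.dataset
        truth = bundle.truth

    observed_vec = popstats.summary_vector(dataset)

    logger.info("stage: reference tables")
    sample_cfg = SampleConfig(
        diploids={p: dataset.genotypes[p].shape[0] for p in dataset.populations},
        sequences={
            p: dataset.sequences[dataset.fragment_names[0]][p].shape[0]
            for p in dataset.populations
        },
    )
    n_sims = int(cfg["n_sims"])
    tolerance = float(cfg["tolerance"])
    if n_sims * tolerance < 10:
        logger.warning(
            "retained set has < 10 rows; regression adjustment is unreliable"
        )
    tables = []
    for i, label in enumerate(cfg["scenarios"]):
        scen = build_builtin_scenario(label)
        table = abcmod.build_reference_table(
            scen, n_sims, sample_cfg, int(stage_seeds[1 + i]), progress=True
        )
        table.save(out / f"reftable_{label}.tsv")
        tables.append(table)

    logger.info("stage: model choice")
    probs = abcmod.model_choice_logistic(tables, observed_vec, tolerance)
    best_label = max(probs, key=probs.get)
    best_table = next(t for t in tables if t.scenario_label == best_label)

    logger.info("stage: parameter estimation (%s)", best_label)
    post = abcmod.estimate_parameters(
        best_table, observed_vec, build_builtin_scenario(best_label), tolerance
    )
    years = abcmod.generations_to_years(
        {k: v for k, v in post.medians.items() if k.startswith("t")}
    )

    logger.info("stage: neutrality / mismatch")
    neutrality_block = {}
    rng_neut = np.random.default_rng(int(stage_seeds[5]))
    for pop in sorted(dataset.populations):
        aln = dataset.concat_sequences(pop)
        entry: dict = {}
        try:
            res = neutrality.neutrality_test(
                aln, n_reps=int(cfg["neutrality_reps"]), rng_seed=rng_neut
            )
            entry.update(
                fs=res.fs, r2=res.r2, p_fs=res.p_fs, p_r2=res.p_r2,
                n=res.n, S=res.s, theta_pi=res.theta_pi,
            )
            spectrum = neutrality.mismatch_observed(aln)
            fit = neutrality.fit_sudden_expansion(spectrum)
            entry["mismatch"] = {
                "tau": fit.tau, "theta0": fit.theta0, "theta1": fit.theta1,
                "ssd": fit.ssd,
            }
        except ValueError as exc:  # monomorphic samples
            entry["error"] = str(exc)
        neutrality_block[pop] = entry

    logger.info("stage: diversity table")
    div = popstats.diversity_table(dataset)
    div.to_csv(out / "diversity_table.tsv", sep="\t")

    report = {
        "seed": seed,
        "stage_seeds": [int(x) for x in stage_seeds],
        "n_sims": n_sims,
        "tolerance": tolerance,
        "truth": truth,
        "scenario_probabilities": probs,
        "chosen_scenario": best_label,
        "posterior_medians": post.medians,
        "posterior_ci95": {k: list(v) for k, v in post.ci95.items()},
        "time_estimates_years": years,
        "neutrality": neutrality_block,
        "diversity_table": str(out / "diversity_table.tsv"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
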