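"""End-to-end orchestration of the stability-conservation analysis.

Stage order mirrors the analysis: burial/interface classification from the
structure, Boltzmann entropies from the ddG scan, Henikoff-weighted
evolutionary entropies from the alignment, entropy-entropy correlation with
the three-set partition, the coevolution scan with the tree-based shuffle
null, per-node phylogenetic conservation profiles, and the lethal/viable
phenotype comparison.  Stages whose inputs are missing are skipped with a
warning; each stage writes its own TSV and a machine-readable summary
collects the headline numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import structure as st
from . import stability as sb
from . import msa as ms
from . import coevolution as cv
from . import phylo as ph

logger = logging.getLogger("stabcons")

__all__ = ["PipelineConfig", "run_full_analysis", "write_pwm_files"]


@dataclass
class PipelineConfig:
    structure_path: str | None = None
    ddg_path: str | None = None
    alignment_path: str | None = None
    phenotype_path: str | None = None
    outdir: str = "stabcons_out"
    temperature_K: float = 300.0
    burial_threshold: float = 1.0
    probe_radius: float = 1.4
    n_dots: int = 1024
    contact_cutoff: float = 4.5
    reference_id: str | None = None
    outlier_evo_min: float = 0.2
    z_min: float = 4.0
    p_max: float = 0.05
    shuffle_iterations: int = 100
    shuffles_per_iteration: int = 2000
    decay_lambda: float | None = None
    max_shuffle_pairs: int = 10
    seed: int = 0
    phenotype_cutoff: float = 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(summary: dict, name: str):
    logger.info("stage %s: start", name)
    summary.setdefault("stages", []).append(name)


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the run summary.

    The summary (also written to ``summary.json``) contains only
    deterministic content — identical config and seed give a byte-identical
    report.  Timestamps go to the log, not the report.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "burial_threshold_A2": config.burial_threshold,
            "contact_cutoff_A": config.contact_cutoff,
            "temperature_K": config.temperature_K,
            "z_min": config.z_min,
            "p_max": config.p_max,
            "phenotype_cutoff_kcal_mol": config.phenotype_cutoff,
        },
    }

    classification = None
    atoms = None
    if config.structure_path:
        _stage(summary, "burial")
        atoms = st.read_structure(Path(config.structure_path).read_text())
        sasa = st.dot_sphere_sasa(atoms, n_dots=config.n_dots,
                                  probe_radius=config.probe_radius)
        buried = st.classify_burial(sasa, config.burial_threshold)
        chains = sorted({a.chain_id for a in atoms})
        pairs = [(a, b) for i, a in enumerate(chains) for b in chains[i + 1:]]
        interface = st.detect_interface_residues(atoms, pairs, config.contact_cutoff)
        classification = st.ResidueClassification(buried, interface,
                                                  config.burial_threshold)
        table = st.classification_table(sasa, classification)
        table.to_csv(out / "burial.tsv", sep="\t", index=False)
        summary["burial"] = {
            "n_residues": len(sasa.per_residue_sasa),
            "n_buried": len(buried),
            "n_interface": len(interface),
        }
    else:
        logger.warning("no structure configured; burial stage skipped")

    profile = None
    scan = None
    if config.ddg_path:
        _stage(summary, "ddg-entropy")
        scan = sb.read_ddg_table(Path(config.ddg_path).read_text(),
                                 temperature_K=config.temperature_K)
        for w in scan.warnings:
            logger.warning("ddg scan: %s", w)
        profile = sb.propensity_profile(scan)
        rows = []
        for key, entry in sorted(profile.entries.items()):
            top3 = sorted(entry.probabilities.items(), key=lambda kv: -kv[1])[:3]
            rows.append({
                "chain": key[0],
                "position": key[1],
                "wt": entry.native_aa,
                "entropy_nats": entry.entropy_nats,
                "entropy_norm": entry.entropy_normalized,
                "top3": ";".join(f"{a}:{p:.3f}" for a, p in top3),
            })
        pd.DataFrame(rows).to_csv(out / "ddg_entropy.tsv", sep="\t", index=False)
        sb.position_weight_matrix(profile).to_csv(out / "ddg_pwm.tsv", sep="\t")
        summary["ddg_entropy"] = {
            "n_positions": len(profile.entries),
            "native_recapitulation": sb.native_recapitulation(scan),
        }
    else:
        logger.warning("no ddG table configured; entropy stage skipped")

    msa = None
    if config.alignment_path:
        _stage(summary, "msa-entropy")
        text = Path(config.alignment_path).read_text()
        fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
        msa = ms.read_alignment(text, fmt)
        ms.henikoff_weights(msa)
        ref = config.reference_id or msa.ids[0]
        msa.set_reference(ref)
        ent = [ms.evolutionary_entropy(msa, j) for j in range(msa.n_columns)]
        evo_df = pd.DataFrame({
            "column": range(msa.n_columns),
            "ref_position": msa.ref_positions,
            "evo_entropy_norm": ent,
        })
        evo_df.to_csv(out / "msa_entropy.tsv", sep="\t", index=False)
        summary["msa_entropy"] = {
            "n_sequences": msa.n_sequences,
            "n_columns": msa.n_columns,
            "reference": ref,
        }
    else:
        logger.warning("no alignment configured; MSA and coevolution stages skipped")

    if profile is not None and msa is not None:
        _stage(summary, "compare")
        chain0 = next(iter(profile.entries))[0]
        positions, evo_vals, calc_vals = [], [], []
        for (chain, pos), entry in sorted(profile.entries.items()):
            if chain != chain0:
                continue
            try:
                col = msa.column_for_position(pos)
            except (KeyError, ValueError):
                continue
            e = ms.evolutionary_entropy(msa, col)
            if np.isnan(e):
                continue
            positions.append(pos)
            evo_vals.append(e)
            calc_vals.append(entry.entropy_normalized)
        if len(positions) >= 3 and np.std(evo_vals) > 0 and np.std(calc_vals) > 0:
            r, p = ms.pearson_with_p(calc_vals, evo_vals)
            part = ms.partition_positions(
                positions, evo_vals, calc_vals,
                outlier_evo_min=config.outlier_evo_min,
            )
            part.table.to_csv(out / "entropy_compare.tsv", sep="\t", index=False)
            _scatter_plot(calc_vals, evo_vals, out / "entropy_scatter.png")
            summary["compare"] = {
                "n_positions": len(positions),
                "pearson_r": r,
                "pearson_p": p,
                "set_counts": part.table["set_label"].value_counts().to_dict(),
                "correlated_slope": part.correlated_slope,
            }
        else:
            logger.warning("compare stage: not enough overlapping variable positions")

    dist = None
    if msa is not None:
        _stage(summary, "coevolve")
        dist = ph.kimura_distance_matrix(msa, on_saturation="cap")
        pairs = cv.zscores_all_pairs(msa)
        spec = cv.ShuffleNullSpec(
            n_iterations=config.shuffle_iterations,
            n_shuffles_per_iteration=config.shuffles_per_iteration,
            decay_lambda=config.decay_lambda,
            seed=config.seed,
        )
        candidates = [p for p in pairs if p.z >= config.z_min]
        for k, pair in enumerate(candidates[: config.max_shuffle_pairs]):
            pair.p_shuffle, _ = cv.tree_shuffle_null(msa, dist, pair.i, pair.j, spec)
        if atoms is not None:
            cv.annotate_spatial_class(pairs, atoms, chain=atoms[0].chain_id)
        sig = cv.significant_pairs(pairs, config.z_min, config.p_max)
        pd.DataFrame([{
            "i": p.i, "j": p.j, "mi": p.mi, "mi_norm": p.mi_norm,
            "z": p.z, "p_shuffle": p.p_shuffle, "spatial_class": p.spatial_class,
        } for p in pairs]).to_csv(out / "coevolution.tsv", sep="\t", index=False)
        summary["coevolve"] = {
            "n_pairs": len(pairs),
            "n_candidates": len(candidates),
            "significant_pairs": [
                {"i": p.i, "j": p.j, "z": round(p.z, 3), "p": p.p_shuffle}
                for p in sig
            ],
        }

    if msa is not None and dist is not None:
        _stage(summary, "phylo-profile")
        tree = ph.neighbor_joining(dist)
        (out / "tree.nwk").write_text(str(tree))
        (out / "distances.phylip").write_text(ph.write_phylip(dist))
        # profile the most variable columns (up to 5)
        ent = [ms.evolutionary_entropy(msa, j) for j in range(msa.n_columns)]
        top_cols = list(np.argsort(ent)[::-1][:5])
        rows = []
        td = {}
        for col in top_cols:
            profiles = ph.node_conservation_profile(tree, msa, int(col))
            td[int(col)] = ph.is_tree_determinant(profiles)
            for np_ in profiles:
                rows.append({
                    "node": np_.node_id, "column": np_.position,
                    "preferred_aa": np_.preferred_aa,
                    "frequency": np_.frequencies.get(np_.preferred_aa, 0.0),
                    "n_leaves": np_.n_leaves,
                })
        pd.DataFrame(rows).to_csv(out / "node_profiles.tsv", sep="\t", index=False)
        summary["phylo_profile"] = {
            "profiled_columns": [int(c) for c in top_cols],
            "tree_determinant": td,
        }

    if config.phenotype_path:
        _stage(summary, "phenotype")
        phen = sb.read_phenotype_table(Path(config.phenotype_path).read_text())
        conf = sb.classify_mutations(phen, cutoff=config.phenotype_cutoff)
        lethal = [m.ddg for m in phen if m.phenotype == "lethal"]
        viable = [m.ddg for m in phen if m.phenotype == "viable"]
        t, p = sb.lethal_viable_ttest(lethal, viable)
        summary["phenotype"] = {
            "n_lethal": len(lethal),
            "n_viable": len(viable),
            "lethal_sensitivity": conf.lethal_sensitivity,
            "viable_specificity": conf.viable_specificity,
            "counts": {
                "true_lethal": conf.true_lethal, "false_viable": conf.false_viable,
                "false_lethal": conf.false_lethal, "true_viable": conf.true_viable,
            },
            "t_statistic": t,
            "one_tailed_p": p,
        }
    else:
        logger.warning("no phenotype table configured; phenotype stage skipped")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", out / "summary.json")
    return summary


def _scatter_plot(calc_vals, evo_vals, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(calc_vals, evo_vals, s=18)
    ax.set_xlabel("stability-derived entropy (H/ln 20)")
    ax.set_ylabel("evolutionary entropy (H/ln 20)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_pwm_files(
    profile, msa: "ms.WeightedMSA", positions: list[int], outdir: str | Path
) -> tuple[Path, Path]:
    """Write paired calculated/evolutionary PWM text files for logo rendering.

    Rows are positions, columns the 20 amino acids; rows sum to 1 and
    unscanned letters are zero.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calc = sb.position_weight_matrix(profile)
    calc_path = outdir / "pwm_calculated.tsv"
    calc.to_csv(calc_path, sep="\t")

    rows = {}
    for pos in positions:
        col = msa.column_for_position(pos)
        freqs = ms.column_frequencies(msa, col)
        rows[str(pos)] = [freqs.get(a, 0.0) for a in sb.AMINO_ACIDS]
    evo = pd.DataFrame.from_dict(rows, orient="index", columns=list(sb.AMINO_ACIDS))
    evo_path = outdir / "pwm_evolutionary.tsv"
    evo.to_csv(evo_path, sep="\t")
    return calc_path, evo_path
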