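"""Reproducible end-to-end runs: simulate, reconstruct, metrics, signal.

Each command takes a :class:`RunConfig`, writes its artefacts under
``config.output_dir`` and embeds the config hash and seed in every manifest
so a rerun with the same config reproduces outputs exactly (single-chain
MCMC mode). The synthetic bundle written by :func:`cmd_simulate` evolves
species-specific landscape peaks along a simulated phylogeny, so the trait
table it emits carries genuine phylogenetic signal for the downstream
analyses to find.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .containers import Calibration, ContourImage
from .mcmc import McmcConfig, fit_phylo_mixed_model, prior_sensitivity
from .nutrigonometry import (
    bootstrap_metrics,
    find_peak_region,
    hypotenuse,
    optimal_pc_ratio,
    validate_reconstruction,
)
from .phylo import blomberg_k
from .reconstruction import reconstruct_from_image
from .synthetic import (
    LandscapeSpec,
    render_contour_image,
    simulate_performance_points,
    simulate_tree,
)

logger = logging.getLogger("nutriphylo")


@dataclass
class RunConfig:
    """Settings for the pipeline commands; YAML-loadable, hash-stamped."""

    output_dir: str = "runs/out"
    seed: int = 0
    # simulate
    n_female_species: int = 9
    n_male_species: int = 5
    n_bands: int = 6
    image_size: tuple[int, int] = (240, 240)
    noise_sd: float = 0.0
    peak_signal_sd: float = 0.35  # sd of BM log-peak displacement across species
    # reconstruct
    jitter_sd: float = 0.25
    min_cluster_pixels: int = 10
    smoothing: float | str = "gcv"
    grid_size: int = 50
    max_points: int = 1200
    # metrics / validation
    q: float = 0.95
    bootstrap_B: int = 1000
    validation_B: int = 200
    # signal
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    tree_path: str | None = None
    traits_path: str | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "mcmc" in raw and isinstance(raw["mcmc"], dict):
            raw["mcmc"] = McmcConfig(**raw["mcmc"])
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed}


def _calibration_dict(cal: Calibration) -> dict:
    return dataclasses.asdict(cal)


def _calibration_from_dict(d: dict) -> Calibration:
    d = dict(d)
    for k in ("protein_pixels", "protein_values", "carb_pixels", "carb_values"):
        d[k] = tuple(d[k])
    return Calibration(**d)


def cmd_simulate(config: RunConfig) -> dict:
    """Write a complete synthetic study bundle with a ground-truth manifest.

    Simulates a pure-birth phylogeny, evolves each species' landscape peak
    along it (Brownian displacement of log peak coordinates, so peaks stay
    positive), samples intake points on diet rails, renders each landscape
    as a banded contour image, and writes points (CSV), images (PNG), the
    tree (Newick) and a species trait table (CSV). Male species are the
    first ``n_male_species`` tips, mirroring a female-biased database.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_female_species, seed=config.seed)
    tree_path = out / "tree.nwk"
    tree.write(path=str(tree_path), schema="newick")

    from .phylo import vcv_from_tree

    cov = vcv_from_tree(tree)
    Cn = cov.matrix / np.max(np.diag(cov.matrix))
    L = np.linalg.cholesky(Cn + 1e-10 * np.eye(len(Cn)))
    z_p = L @ rng.standard_normal(len(Cn))
    z_c = L @ rng.standard_normal(len(Cn))

    species = cov.labels
    male_species = species[: config.n_male_species]
    landscapes = []
    trait_rows = []
    for i, sp in enumerate(species):
        sexes = ["female"] + (["male"] if sp in male_species else [])
        for sex in sexes:
            shift = 0.0 if sex == "female" else rng.normal(0.0, 0.1)
            peak_p = 2.0 * np.exp(config.peak_signal_sd * z_p[i] + shift)
            peak_c = 4.0 * np.exp(config.peak_signal_sd * z_c[i] - shift)
            spec = LandscapeSpec(
                peak_p=float(peak_p),
                peak_c=float(peak_c),
                noise_sd=config.noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            points = simulate_performance_points(spec)
            image, truth = render_contour_image(
                points, n_bands=config.n_bands, image_size=config.image_size
            )
            stem = f"{sp}_{sex}"
            points.to_csv(out / f"points_{stem}.csv", index=False)
            Image.fromarray(image.pixels).save(out / f"image_{stem}.png")
            landscapes.append(
                {
                    "species": sp,
                    "sex": sex,
                    "points": f"points_{stem}.csv",
                    "image": f"image_{stem}.png",
                    "true_peak": [spec.peak_p, spec.peak_c],
                    "band_value_map": {
                        str(k): v for k, v in image.band_value_map.items()
                    },
                    "calibration": _calibration_dict(image.calibration),
                    "n_bands": config.n_bands,
                }
            )
            pc = spec.peak_p / spec.peak_c
            trait_rows.append((sp, "optimal_pc_ratio", pc, "s1", sex))
            trait_rows.append(
                (
                    sp,
                    "self_regulated_pc_ratio",
                    pc * np.exp(rng.normal(0.0, 0.2)),
                    "s1",
                    sex,
                )
            )
    # cross-sex trade-off traits, defined only where both sexes exist
    by_key = {(l["species"], l["sex"]): l for l in landscapes}
    for sp in male_species:
        f = by_key[(sp, "female")]["true_peak"]
        m = by_key[(sp, "male")]["true_peak"]
        theta = float(
            np.degrees(np.arctan2(f[0], f[1]) - np.arctan2(m[0], m[1]))
        )
        trait_rows.append((sp, "theta", theta, "s1", "both"))
        trait_rows.append((sp, "hypotenuse", float(np.hypot(*f)), "s1", "both"))

    traits = pd.DataFrame(
        trait_rows, columns=["species", "trait", "value", "study", "sex"]
    )
    traits.to_csv(out / "traits.csv", index=False)
    manifest = {
        **_stamp(config),
        "tree": "tree.nwk",
        "traits": "traits.csv",
        "landscapes": landscapes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("simulate: wrote %d landscapes to %s", len(landscapes), out)
    return manifest


def _load_image(path: Path, entry: dict) -> ContourImage:
    pixels = np.asarray(Image.open(path).convert("RGB"))
    return ContourImage(
        pixels=pixels,
        calibration=_calibration_from_dict(entry["calibration"]),
        band_value_map={int(k): float(v) for k, v in entry["band_value_map"].items()},
    )


def cmd_reconstruct(config: RunConfig) -> dict:
    """Reconstruct every landscape of a simulated bundle and validate it.

    Reads the manifest written by :func:`cmd_simulate`, runs the full
    extraction on each image, and compares the reconstructed landscape with
    the original points via the bootstrap overlap test. Writes per-landscape
    reconstructed points (CSV) and a reconstruction report (JSON).
    """
    out = Path(config.output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    reports = []
    for entry in manifest["landscapes"]:
        stem = f"{entry['species']}_{entry['sex']}"
        step = "load"
        try:
            image = _load_image(out / entry["image"], entry)
            original = pd.read_csv(out / entry["points"])
            step = "reconstruct"
            points, landscape, log = reconstruct_from_image(
                image,
                n_colors=entry["n_bands"],
                jitter_sd=config.jitter_sd,
                min_cluster_pixels=config.min_cluster_pixels,
                smoothing=config.smoothing,
                grid_size=config.grid_size,
                max_points=config.max_points,
                seed=config.seed,
            )
            points.to_csv(out / f"reconstructed_{stem}.csv", index=False)
            step = "validate"
            report = validate_reconstruction(
                original,
                landscape.points,
                B=config.validation_B,
                q=config.q,
                seed=config.seed,
                smoothing=landscape.smoothing,
                grid_size=config.grid_size,
            )
            region = find_peak_region(landscape, q=config.q)
            reports.append(
                {
                    "landscape": stem,
                    "log": log,
                    "pc_ratio": optimal_pc_ratio(region),
                    "hypotenuse": hypotenuse(region),
                    "centroid": list(region.centroid),
                    "true_peak": entry["true_peak"],
                    **report,
                }
            )
            logger.info("reconstruct %s: %s", stem, report["verdict"])
        except Exception as exc:
            raise RuntimeError(
                f"landscape {stem}: step '{step}' failed: {exc}"
            ) from exc
    result = {**_stamp(config), "reports": reports}
    (out / "reconstruction_report.json").write_text(
        json.dumps(result, indent=2, default=float)
    )
    return result


def cmd_metrics(config: RunConfig, points_path: str) -> dict:
    """Bootstrap trade-off metrics for one point table (CSV in, JSON out)."""
    points = pd.read_csv(points_path)
    m = bootstrap_metrics(
        points,
        B=config.bootstrap_B,
        q=config.q,
        seed=config.seed,
        smoothing=config.smoothing,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = {
        **_stamp(config),
        "points": str(points_path),
        "pc_ratio": m.pc_ratio,
        "hypotenuse": m.hypotenuse,
        "ci": {k: list(v) for k, v in m.ci.items()},
        "n_boot": m.n_boot,
        "n_skipped": m.n_skipped,
    }
    name = Path(points_path).stem
    (out / f"metrics_{name}.json").write_text(json.dumps(result, indent=2))
    return result


def cmd_validate(config: RunConfig, original_path: str, reconstructed_path: str) -> dict:
    """Bootstrap overlap test between two point tables (CSV in, JSON out)."""
    report = validate_reconstruction(
        pd.read_csv(original_path),
        pd.read_csv(reconstructed_path),
        B=config.validation_B,
        q=config.q,
        seed=config.seed,
        smoothing=config.smoothing,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = {**_stamp(config), **report}
    (out / "validation_report.json").write_text(
        json.dumps(result, indent=2, default=float)
    )
    return result


def read_tree(path) -> dendropy.Tree:
    """Read a Newick tree, treating it as rooted."""
    return dendropy.Tree.get(
        path=str(path), schema="newick", rooting="force-rooted"
    )


def cmd_signal(config: RunConfig, sensitivity: bool = False) -> dict:
    """Phylogenetic-signal reports per trait and sex.

    For every (trait, sex) group with at least four species, reports
    Blomberg's K with its permutation p-value and the posterior of Pagel's
    lambda from the mixed model (R-hat per component when >= 2 chains).
    Repeated observations are averaged per species for K; the mixed model
    consumes them directly. Sexes are analysed separately.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_tree(config.tree_path or out / "tree.nwk")
    traits = pd.read_csv(config.traits_path or out / "traits.csv")
    tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    offenders = sorted(set(traits["species"]) - tip_labels)
    if offenders:
        raise ValueError(f"species absent from the tree: {offenders}")

    reports = []
    for (trait, sex), grp in traits.groupby(["trait", "sex"]):
        means = grp.groupby("species")["value"].mean()
        if len(means) < 4:
            logger.info("signal: skipping %s/%s (<4 species)", trait, sex)
            continue
        sub_taxa = set(means.index)
        sub_tree = tree.extract_tree_with_taxa_labels(sub_taxa)
        sub_tree.is_rooted = True
        kb = blomberg_k(sub_tree, means, seed=config.seed)
        lam = fit_phylo_mixed_model(
            grp, sub_tree, config=config.mcmc, trait=trait, sex=sex
        )
        report = {
            "trait": trait,
            "sex": sex,
            "n_species": len(means),
            "blomberg_K": kb.K,
            "p_perm": kb.p_perm,
            "lambda_mean": lam.lambda_mean,
            "lambda_hpd": list(lam.lambda_hpd),
            "rhat": lam.rhat,
            "autocorr_lag1": lam.autocorr_lag1,
            "converged": lam.converged,
            "notes": lam.notes,
        }
        if sensitivity:
            tab = prior_sensitivity(
                grp, sub_tree, config=config.mcmc, trait=trait, sex=sex
            )
            report["prior_sensitivity"] = tab.to_dict(orient="records")
        reports.append(report)
    result = {**_stamp(config), "reports": reports}
    (out / "signal_report.json").write_text(
        json.dumps(result, indent=2, default=float)
    )
    return result
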