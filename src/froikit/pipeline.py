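"""End-to-end orchestration: simulate -> spaces -> fROI -> reliability ->
group GLM -> permutation tests -> whole-brain, from one YAML config.

Every stage seed is explicit in the config; rerunning with the same
config reproduces every report byte-identically.  A manifest records
versions, seeds and input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .froi import FroiConfig, define_froi, froi_table
from .group_stats import (build_design, correct_p, fit_binomial_glm,
                          fit_gaussian_glm, FULL_PREDICTORS,
                          PerfectSeparationError)
from .hypothesis_space import build_spaces_for_half, split_sample
from .permutation import matched_mean_test, matched_variance_test
from .reliability import reliability_report
from .synthetic import (CohortConfig, NoiseSpec, REGION_CENTERS_MM,
                        default_blobs, generate_cohort,
                        simulate_cohort_maps, write_truth)
from .volumes import mni_grid, write_volume
from .wholebrain import clusters_at_threshold, validate_in_heldout, \
    voxelwise_group_diff_tmap

log = logging.getLogger("froikit")

TREND_P = 0.01  # uncorrected p below this is reported as a 'trend'

#: tolerance for pairwise matching of ASD to NT controls
MATCH_TOLERANCES = {"age": 5.0, "iq": 10.0}

#: per-analysis-sample predictor sets and correction factors
SAMPLE_DEFINITIONS = {
    "full": {"predictors": FULL_PREDICTORS, "m": 6,
             "interest": ("group",)},
    "matched": {"predictors": ("age", "gender", "group", "modality",
                               "n_stimuli", "mean_words", "task_type",
                               "iq"),
                "m": 6, "interest": ("group",)},
    "iq": {"predictors": ("age", "gender", "group", "modality",
                          "n_stimuli", "mean_words", "task_type", "iq"),
           "m": 6, "interest": ("iq",)},
    "asd": {"predictors": ("age", "gender", "modality", "n_stimuli",
                           "mean_words", "task_type", "ados_comm",
                           "ados_soc"),
            "m": 12, "interest": ("ados_comm", "ados_soc")},
}


@dataclass
class PipelineConfig:
    out_dir: str = "froikit_out"
    seed_cohort: int = 11
    seed_noise: int = 12
    seed_split: int = 13
    seed_perm: int = 14
    n_nt: int = 462
    n_asd: int = 31
    grid_dims: tuple = (40, 48, 40)
    voxel_mm: float = 4.0
    regions: tuple = ("RTPJ", "LTPJ", "PC", "DMPFC", "MMPFC", "VMPFC",
                      "RSTS")
    group_delta: float = 0.0
    iq_pc_slope: float = 0.0
    noise_sd: float = 1.0
    noise_smooth_fwhm_mm: float = 0.0
    map_df: int = 100
    froi: FroiConfig = field(default_factory=FroiConfig)
    n_perm_reliability: int = 5000
    n_perm_matched: int = 25000
    samples: tuple = ("full", "matched")
    write_maps: bool = False
    wholebrain_min_size: int = 0
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        froi_cfg = FroiConfig(**payload.pop("froi", {}))
        cfg = cls(froi=froi_cfg, **payload)
        return cfg


def build_matched_pairs(cohort: pd.DataFrame,
                        tolerances=MATCH_TOLERANCES) -> pd.DataFrame:
    """Greedy one-to-one matching of ASD to NT controls.

    Pairs must share gender, coil, modality and task type, and differ by
    at most 5 years in age and 10 IQ points; both members need a
    recorded IQ.  ASD participants without an admissible control are
    dropped (with a log line), mirroring how unmatched cases are
    excluded.  Returns the matched subset with a ``pair`` column.
    """
    nt = cohort[(cohort.group == "NT") & cohort.iq.notna()].copy()
    rows = []
    used = set()
    for _, asd in cohort[(cohort.group == "ASD")
                         & cohort.iq.notna()].iterrows():
        pool = nt[(~nt.id.isin(used))
                  & (nt.gender == asd.gender)
                  & (nt.coil == asd.coil)
                  & (nt.modality == asd.modality)
                  & (nt.task_type == asd.task_type)
                  & ((nt.age - asd.age).abs() <= tolerances["age"])
                  & ((nt.iq - asd.iq).abs() <= tolerances["iq"])]
        if pool.empty:
            log.info("ASD participant %s could not be matched", asd.id)
            continue
        cost = ((pool.age - asd.age).abs() / tolerances["age"]
                + (pool.iq - asd.iq).abs() / tolerances["iq"])
        best = pool.loc[cost.idxmin()]
        used.add(best.id)
        pair_id = f"pair-{len(rows):03d}"
        for rec in (asd, best):
            row = rec.to_dict()
            row["pair"] = pair_id
            rows.append(row)
    matched = pd.DataFrame(rows)
    if not matched.empty:
        _assert_pair_tolerances(matched, tolerances)
    return matched


def _assert_pair_tolerances(matched: pd.DataFrame, tolerances) -> None:
    for _, pair in matched.groupby("pair"):
        assert len(pair) == 2
        a, b = pair.iloc[0], pair.iloc[1]
        assert a.gender == b.gender
        assert abs(a.age - b.age) <= tolerances["age"] + 1e-9
        assert abs(a.iq - b.iq) <= tolerances["iq"] + 1e-9


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output paths.

    Any stage failure propagates with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "simulate"
    try:
        grid = mni_grid(config.grid_dims, config.voxel_mm)
        cohort_cfg = CohortConfig(n_nt=config.n_nt, n_asd=config.n_asd,
                                  **config.cohort_overrides)
        cohort = generate_cohort(cohort_cfg, seed=config.seed_cohort)
        cohort_path = out / "cohort.csv"
        cohort.to_csv(cohort_path, index=False)
        paths["cohort"] = str(cohort_path)

        blobs = [b for b in default_blobs(group_delta=config.group_delta,
                                          iq_pc_slope=config.iq_pc_slope)
                 if b.name in config.regions]
        noise = NoiseSpec(sd=config.noise_sd,
                          smooth_fwhm_mm=config.noise_smooth_fwhm_mm)
        subjects = {}
        truths = []
        for record, even, odd, truth in simulate_cohort_maps(
                cohort, blobs, noise, grid, seed=config.seed_noise,
                df=config.map_df):
            subjects[record["id"]] = (record, even, odd)
            truths.append(truth)
            if config.write_maps:
                write_volume(even, out / "maps" / f"{record['id']}_even.nii.gz")
                write_volume(odd, out / "maps" / f"{record['id']}_odd.nii.gz")
        write_truth(truths, out / "truth.json")
        paths["truth"] = str(out / "truth.json")

        stage = "spaces"
        half1, half2 = split_sample(cohort, seed=config.seed_split)
        seed_points = {r: c for r, c in REGION_CENTERS_MM.items()
                       if r in config.regions}
        # combined even+odd maps drive the group RFX per half
        def _full_maps(half):
            from .volumes import ScalarVolume
            vols = []
            for sid in half["id"]:
                _, even, odd = subjects[sid]
                vols.append(ScalarVolume(grid, (even.values + odd.values) / 2,
                                         df=config.map_df))
            return vols
        spaces1 = build_spaces_for_half(_full_maps(half1), 1,
                                        seed_points=seed_points)
        spaces2 = build_spaces_for_half(_full_maps(half2), 2,
                                        seed_points=seed_points)
        for name, space in {**{f"{k}_half1": v for k, v in spaces1.items()},
                            **{f"{k}_half2": v
                               for k, v in spaces2.items()}}.items():
            write_volume(space.mask, out / "spaces" / f"{name}.nii.gz")

        stage = "froi"
        # cross-definition: spaces from half 1 applied to half 2 subjects
        results_even, results_odd, results_full = {}, {}, {}
        half1_ids = set(half1["id"])
        for half, spaces in ((half1, spaces2), (half2, spaces1)):
            for sid in half["id"]:
                _, even, odd = subjects[sid]
                full = type(even)(grid, (even.values + odd.values) / 2,
                                  df=config.map_df)
                for space in spaces.values():
                    # cross-definition guard: a space may never be applied
                    # to a subject from the half it was built in
                    subject_half = 1 if sid in half1_ids else 2
                    assert space.source_half != subject_half, (
                        f"space {space.name} from half {space.source_half} "
                        f"applied to subject {sid} of the same half")
                results_even[sid] = {n: define_froi(even, s, config.froi)
                                     for n, s in spaces.items()}
                results_odd[sid] = {n: define_froi(odd, s, config.froi)
                                    for n, s in spaces.items()}
                results_full[sid] = {n: define_froi(full, s, config.froi)
                                     for n, s in spaces.items()}
        even_table = froi_table(results_even)
        odd_table = froi_table(results_odd)
        full_table = froi_table(results_full)
        even_table.to_csv(out / "params_even.csv", index=False)
        odd_table.to_csv(out / "params_odd.csv", index=False)
        full_table.to_csv(out / "params.csv", index=False)
        paths["params"] = str(out / "params.csv")

        stage = "reliability"
        rel = reliability_report(even_table, odd_table,
                                 n_perm=config.n_perm_reliability,
                                 seed=config.seed_perm)
        rel.to_csv(out / "reliability.csv", index=False)
        paths["reliability"] = str(out / "reliability.csv")

        stage = "glm"
        matched = build_matched_pairs(cohort)
        matched.to_csv(out / "matched.csv", index=False)
        glm_rows = []
        for sample in config.samples:
            spec = SAMPLE_DEFINITIONS[sample]
            records = matched if sample == "matched" else cohort
            if sample == "iq":
                records = cohort[cohort.iq.notna()]
            if sample == "asd":
                records = cohort[cohort.group == "ASD"]
            if records.empty:
                continue
            glm_rows.extend(_glm_sample(full_table, records, sample, spec))
        glm_df = pd.DataFrame(glm_rows)
        glm_df.to_csv(out / "glm.csv", index=False)
        paths["glm"] = str(out / "glm.csv")

        stage = "permtest"
        perm_rows = []
        if not matched.empty and matched.group.nunique() == 2:
            labels_by_id = matched.set_index("id")["group"]
            for region, sub in full_table.groupby("region"):
                sub = sub[sub.id.isin(labels_by_id.index)]
                if sub.empty:
                    continue
                labels = labels_by_id.loc[sub["id"]].to_numpy()
                if pd.Series(labels).nunique() < 2 or len(labels) < 4:
                    log.warning("permtest %s: matched sample too small",
                                region)
                    continue
                try:
                    for res in matched_mean_test(
                            sub, labels, n_perm=config.n_perm_matched,
                            seed=config.seed_perm, region=region):
                        row = asdict(res); row["test"] = "mean"
                        perm_rows.append(row)
                except ValueError as exc:
                    log.warning("permtest %s: %s", region, exc)
                try:
                    for res in matched_variance_test(
                            sub, labels, n_perm=config.n_perm_matched,
                            seed=config.seed_perm + 1, region=region):
                        row = asdict(res); row["test"] = "variance"
                        perm_rows.append(row)
                except ValueError:
                    pass
        pd.DataFrame(perm_rows).to_csv(out / "permtest.csv", index=False)
        paths["permtest"] = str(out / "permtest.csv")

        stage = "wholebrain"
        wb_rows = []
        nt_ids = cohort[cohort.group == "NT"]["id"]
        asd_ids = cohort[cohort.group == "ASD"]["id"]
        halves = {
            "even": ([subjects[s][1] for s in nt_ids],
                     [subjects[s][1] for s in asd_ids]),
            "odd": ([subjects[s][2] for s in nt_ids],
                    [subjects[s][2] for s in asd_ids]),
        }
        for disc, heldout in (("even", "odd"), ("odd", "even")):
            tmap = voxelwise_group_diff_tmap(*halves[disc])
            for direction in (1, -1):
                clusters = clusters_at_threshold(
                    tmap, min_size=config.wholebrain_min_size,
                    discovery_half=disc, direction=direction)
                validated = validate_in_heldout(clusters, *halves[heldout],
                                                heldout_half=heldout)
                for c in validated:
                    wb_rows.append({
                        "discovery_half": disc,
                        "direction": "NT>ASD" if direction == 1
                        else "ASD>NT",
                        "peak_x": c.peak_mm[0], "peak_y": c.peak_mm[1],
                        "peak_z": c.peak_mm[2], "peak_t": c.peak_t,
                        "size": c.size, "validation_p": c.validation_p,
                        "validated": c.validated})
        pd.DataFrame(wb_rows).to_csv(out / "wholebrain.csv", index=False)
        paths["wholebrain"] = str(out / "wholebrain.csv")

        stage = "manifest"
        manifest = {
            "froikit_version": __version__,
            "numpy_version": np.__version__,
            "seeds": {"cohort": config.seed_cohort,
                      "noise": config.seed_noise,
                      "split": config.seed_split,
                      "perm": config.seed_perm},
            "hashes": {k: _file_hash(Path(v)) for k, v in paths.items()
                       if Path(v).is_file()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        paths["manifest"] = str(out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths


def _glm_sample(param_table: pd.DataFrame, records: pd.DataFrame,
                sample: str, spec: dict) -> list[dict]:
    rows = []
    records = records.set_index("id", drop=False)
    try:
        design = build_design(records, spec["predictors"])
    except (KeyError, ValueError) as exc:
        log.warning("sample %s: design not buildable (%s)", sample, exc)
        return rows
    for region, sub in param_table.groupby("region"):
        sub = sub[sub.id.isin(design.index)].set_index("id")
        sub = sub.reindex(design.index)
        for param in ("mean_t", "size", "com_x", "com_y", "com_z"):
            try:
                fits = fit_gaussian_glm(sub[param], design, records,
                                        parameter=param, m=spec["m"])
            except ValueError as exc:
                log.warning("%s/%s/%s: %s", sample, region, param, exc)
                continue
            rows.extend(_fit_rows(fits, sample, region, spec))
        try:
            fits = fit_binomial_glm(sub["found"], design, records, m=spec["m"])
            rows.extend(_fit_rows(fits, sample, region, spec))
        except (ValueError, PerfectSeparationError) as exc:
            log.warning("%s/%s/found: %s", sample, region, exc)
    return rows


def _fit_rows(fits: dict, sample: str, region: str, spec: dict) -> list[dict]:
    rows = []
    for fit in fits.values():
        row = asdict(fit)
        row.update(sample=sample, region=region,
                   of_interest=fit.predictor in spec["interest"],
                   trend=fit.p_uncorrected < TREND_P)
        row["ci99_low"], row["ci99_high"] = row.pop("ci99")
        rows.append(row)
    return rows
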