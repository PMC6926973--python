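"""End-to-end pipeline: simulate/load → clean → learn → evaluate → report.

One YAML config drives all stages; every run writes a manifest carrying the
config hash and the seeds, so a rerun with an identical config yields
byte-identical machine outputs.  On a stage failure all partial outputs are
removed and the failing stage is named.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import yaml

from . import bn, evaluation, learn, preprocess, sensitivity, synthetic, whatif
from .errors import BnWhatIfError, ConfigError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "learn", "evaluate", "sensitivity", "whatif")


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return payload


def config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def validate_config(config: Mapping, base_dir: Path) -> None:
    """Fail fast (before any stage runs) on structural config problems."""
    unknown = set(config) - {"seed", "input", *STAGE_ORDER}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    if "input" not in config and "simulate" not in config:
        raise ConfigError("config needs either 'input' or a 'simulate' section")
    if "input" in config and not (base_dir / str(config["input"])).exists():
        raise ConfigError(f"input file {config['input']!r} does not exist")
    for scenario_path in (config.get("whatif") or {}).get("scenarios", []):
        if not (base_dir / str(scenario_path)).exists():
            raise ConfigError(f"scenario file {scenario_path!r} does not exist")
    learn_block = config.get("learn") or {}
    learn.LearnerConfig.from_dict(
        {k: v for k, v in learn_block.items() if k != "class_var"}
    )


def run_pipeline(config: Mapping, outdir, base_dir=None) -> dict:
    """Execute the stages in order and return the artifact manifest.

    Stage order: preprocess → learn (full and MB-restricted) → evaluate →
    sensitivity → what-if.  Data comes from ``input`` (a survey CSV) or the
    ``simulate`` block (a named fixture sampled with injected corruption).
    """
    outdir = Path(outdir)
    base_dir = Path(base_dir) if base_dir is not None else Path.cwd()
    validate_config(config, base_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    written: list[Path] = []
    artifacts: dict[str, str] = {}
    stage = "setup"

    def emit(name: str, path: Path) -> Path:
        written.append(path)
        artifacts[name] = str(path)
        return path

    try:
        # --- simulate / load -------------------------------------------------
        stage = "simulate"
        sim = config.get("simulate")
        if sim is not None:
            net0 = synthetic.get_fixture(
                str(sim.get("fixture", "survey11")), int(sim.get("seed", seed))
            )
            corruption = synthetic.CorruptionSpec(
                missing_rate=float(sim.get("missing", 0.0)),
                nonuser_rate=float(sim.get("nonuser", 0.0)),
                dontknow_rate=float(sim.get("dontknow", 0.0)),
                seed=int(sim.get("seed", seed)),
            )
            raw, log = synthetic.generate_survey(
                net0, int(sim.get("n", 1000)), corruption
            )
            synthetic.save_injection_log(
                log, emit("injection_log", outdir / "injection_log.json")
            )
            preprocess.write_survey_csv(raw, emit("raw_data", outdir / "raw.csv"))
        else:
            raw = preprocess.read_survey_csv(base_dir / str(config["input"]))

        # --- preprocess ------------------------------------------------------
        stage = "preprocess"
        pp = config.get("preprocess") or {}
        markers = pp.get("missing_markers", sorted(preprocess.MISSING_MARKERS))
        phone = pp.get("smartphone")
        rules = None
        if phone:
            rules = preprocess.SmartphoneRules(
                column=str(phone["column"]),
                nonuser_tokens=frozenset(
                    phone.get("nonuser_tokens", [preprocess.NON_USER_TOKEN])
                ),
                dontknow_tokens=frozenset(
                    phone.get("dontknow_tokens", [preprocess.DONT_KNOW_TOKEN])
                ),
            )
        cleaned, report = preprocess.filter_rows(raw, markers, rules)
        logger.info(
            "filter: in=%d missing=%d nonuser=%d dontknow=%d out=%d",
            report.rows_in,
            report.rows_dropped_missing,
            report.rows_dropped_nonuser,
            report.rows_dropped_dontknow,
            report.rows_out,
        )
        merges = [
            preprocess.MergeSpec(
                new_name=m["new_name"],
                source_columns=tuple(m["source_columns"]),
                combine=m.get("combine", "ordinal_sum"),
                bins=int(m.get("bins", 3)),
            )
            for m in pp.get("merges", [])
        ]
        if merges:
            cleaned = preprocess.merge_attributes(cleaned, merges)
        preprocess.write_survey_csv(
            cleaned, emit("cleaned_data", outdir / "cleaned.csv")
        )

        # --- learn -----------------------------------------------------------
        stage = "learn"
        learn_block = dict(config.get("learn") or {})
        class_var = str(learn_block.pop("class_var", synthetic.TARGET_VARIABLE))
        lconfig = learn.LearnerConfig.from_dict({"seed": seed, **learn_block})
        gbn = learn.learn_structure(cleaned, lconfig)
        bn.save_network(gbn, emit("network", outdir / "network.json"))
        gbn_mb, selection = learn.gbn_mb_classifier(cleaned, class_var, lconfig)
        bn.save_network(gbn_mb, emit("network_mb", outdir / "network_mb.json"))
        logger.info(
            "markov blanket of %s: kept=%s discarded=%s",
            class_var,
            sorted(selection.blanket),
            sorted(selection.discarded),
        )

        # --- evaluate ----------------------------------------------------
        stage = "evaluate"
        ev = config.get("evaluate")
        if ev is not None:
            results = evaluation.evaluate_models(
                cleaned,
                class_var,
                models=tuple(ev.get("models", evaluation.KNOWN_MODELS)),
                k=int(ev.get("folds", 10)),
                seed=seed,
                config=lconfig,
            )
            evaluation.write_evaluation_tsv(
                results, emit("evaluation", outdir / "evaluation.tsv")
            )

        # --- sensitivity ---------------------------------------------------
        stage = "sensitivity"
        sens = config.get("sensitivity")
        if sens is not None:
            target = str(sens.get("target", class_var))
            rows = sensitivity.sensitivity_to_findings(gbn, target)
            sensitivity.write_sensitivity_tsv(
                rows, emit("sensitivity", outdir / "sensitivity.tsv")
            )

        # --- what-if ---------------------------------------------------------
        stage = "whatif"
        wi = config.get("whatif")
        if wi is not None:
            arrow_lines = []
            for scenario_path in wi.get("scenarios", []):
                for scenario in whatif.load_scenarios(
                    base_dir / str(scenario_path), gbn
                ):
                    report_ = whatif.apply_scenario(gbn, scenario)
                    whatif.save_report(
                        report_,
                        emit(
                            f"scenario_{scenario.name}",
                            outdir / f"scenario_{scenario.name}.json",
                        ),
                        scenario.name,
                    )
                    arrow_lines.append(
                        f"{scenario.name}\t{whatif.format_arrow(report_)}"
                    )
            if arrow_lines:
                path = emit("scenario_table", outdir / "scenarios.txt")
                path.write_text("\n".join(arrow_lines) + "\n", encoding="utf-8")

        # --- manifest --------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config_hash": config_hash(config),
            "seed": seed,
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
        )
        return manifest
    except BnWhatIfError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise BnWhatIfError(f"stage {stage!r} failed: {exc}") from exc
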