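"""Command-line interface, run configuration, and windowing utilities.

Subcommands: ``simulate | walk | dipfilter | gwas | evaluate``.  Every run
writes a ``manifest.json`` (configuration, seeds, package version, input
checksums) next to its outputs so results can be reproduced byte for byte.
User-facing genomic coordinates are 1-based inclusive; internal indices are
0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .arg_graph import load_arg, read_edge_list, read_leaf_labels
from .hotspot_gwas import GWAS_THRESHOLD, gwas_scan, maf_filter
from .popsim import Scenario, read_sample, simulate_sample, write_sample
from .rw_engine import read_profile, walk_profile, write_profile
from .unimodality_filter import DIP_THRESHOLD, filter_hotspots, write_report

logger = logging.getLogger("argwalker")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and dialect flags shared across subcommands."""

    dip_threshold: float = DIP_THRESHOLD
    gwas_threshold: float = GWAS_THRESHOLD
    mhc_threshold: float = 5e-8
    maf_floor: float = 0.01
    window_width: int = 100
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if min(self.dip_threshold, self.gwas_threshold, self.mhc_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.window_width < 3:
            raise ValueError("window width must be >= 3")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {k: data.pop(k) for k in list(data) if k in cls.__dataclass_fields__}
        cfg = cls(**known, extra=data) if data else cls(**known)
        cfg.validate()
        return cfg

    def to_toml(self, path) -> None:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            return '"' + str(v).replace('"', '\\"') + '"'

        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                if k == "extra":
                    for ek, ev in v.items():
                        fh.write(f"{ek} = {fmt(ev)}\n")
                else:
                    fh.write(f"{k} = {fmt(v)}\n")


def extract_windows(
    matrix: np.ndarray,
    positions: np.ndarray,
    hotspot_positions,
    width: int = 100,
):
    """Cut a `width`-SNP window around each hotspot; drop overlapping windows.

    Each window is centred on the SNP nearest the hotspot position
    (symmetric; truncated with a warning at chromosome ends).  Windows are
    processed in genomic order and a window overlapping an already accepted
    one is dropped (greedy left-to-right), mirroring the practice of
    filtering overlapped haplotype windows.  Hotspots outside the SNP span
    are skipped with a warning.

    Returns a list of ``(hotspot_position, snp_slice, sub_matrix)`` tuples.
    """
    n_snps = matrix.shape[1]
    out = []
    last_end = 0
    for hp in sorted(hotspot_positions):
        if hp < positions[0] or hp > positions[-1]:
            warnings.warn(f"hotspot at {hp} outside the SNP span, skipped")
            continue
        centre = int(np.argmin(np.abs(positions - hp)))
        start = centre - width // 2
        end = start + width
        if start < 0 or end > n_snps:
            warnings.warn(f"window for hotspot at {hp} truncated at chromosome end")
            start, end = max(0, start), min(n_snps, end)
        if start < last_end:
            logger.info("window for hotspot at %s overlaps previous one: dropped", hp)
            continue
        out.append((hp, slice(start, end), matrix[:, start:end]))
        last_end = end
    return out


# ------------------------------------------------------------------ CLI


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir, command: str, params: dict, inputs: list) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "version": __version__,
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


@click.group(name="argwalker")
@click.version_option(__version__)
def cli() -> None:
    """Individual-specific recombination hotspot strengths from ARGs."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")


@cli.command()
@click.option("--scenario", "scenario_file", type=click.Path(exists=True),
              help="TOML file of Scenario fields.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(scenario_file, seed, out_dir):
    """Simulate a two-allele hotspot sample (haplotypes, truth, true ARG)."""
    kw = {}
    if scenario_file:
        with open(scenario_file, "rb") as fh:
            kw = tomllib.load(fh)
    kw["seed"] = seed
    sc = Scenario(**kw)
    sample = simulate_sample(sc)
    write_sample(sample, out_dir)
    _write_manifest(out_dir, "simulate", {"scenario": kw},
                    [scenario_file] if scenario_file else [])
    click.echo(f"wrote sample ({sample.n_hap} haplotypes, "
               f"{sample.matrix.shape[1]} SNPs) to {out_dir}")


@cli.command()
@click.option("--arg", "arg_file", required=True, type=click.Path(exists=True))
@click.option("--labels", "labels_file", required=True, type=click.Path(exists=True))
@click.option("--out", "out_file", required=True, type=click.Path())
@click.option("--hotspot-id", default="hotspot", show_default=True)
@click.option("--reverse-edges", is_flag=True,
              help="Input edges are descendant→ancestor; flip them.")
def walk(arg_file, labels_file, out_file, hotspot_id, reverse_edges):
    """Run the backward-forward walker on an ARG edge list."""
    g = load_arg(read_edge_list(arg_file), read_leaf_labels(labels_file),
                 reverse=reverse_edges)
    profile = walk_profile(g, hotspot_id)
    write_profile(profile, out_file)
    _write_manifest(Path(out_file).parent, "walk",
                    {"arg": str(arg_file), "labels": str(labels_file),
                     "hotspot_id": hotspot_id},
                    [arg_file, labels_file])
    click.echo(f"wrote profile for {len(profile.strengths)} haplotypes to {out_file}")


@cli.command()
@click.option("--profiles", "profile_files", required=True, multiple=True,
              type=click.Path(exists=True), help="Profile TSVs (repeatable).")
@click.option("--threshold", type=float, default=DIP_THRESHOLD, show_default=True)
@click.option("--n-null", type=int, default=10_000, show_default=True)
@click.option("--seed", type=int, default=20150901, show_default=True)
@click.option("--out", "out_file", required=True, type=click.Path())
def dipfilter(profile_files, threshold, n_null, seed, out_file):
    """Dip-test strength profiles; keep those with -log10(p) >= threshold."""
    profiles = [read_profile(p) for p in profile_files]
    report = filter_hotspots(profiles, threshold, n_null=n_null, seed=seed)
    write_report(report, out_file)
    _write_manifest(Path(out_file).parent, "dipfilter",
                    {"threshold": threshold, "n_null": n_null, "seed": seed},
                    list(profile_files))
    kept = int((report["decision"] == "keep").sum())
    click.echo(f"kept {kept}/{len(report)} profiles at -log10(p) >= {threshold}")


@cli.command()
@click.option("--profiles", "profile_files", required=True, multiple=True,
              type=click.Path(exists=True))
@click.option("--genotypes", "genotype_file", required=True,
              type=click.Path(exists=True),
              help="Haplotype TSV as written by `simulate` (haplotypes.tsv).")
@click.option("--threshold", type=float, default=GWAS_THRESHOLD, show_default=True)
@click.option("--maf-floor", type=float, default=0.01, show_default=True)
@click.option("--welch", is_flag=True, help="Welch instead of pooled-variance test.")
@click.option("--out", "out_file", required=True, type=click.Path())
def gwas(profile_files, genotype_file, threshold, maf_floor, welch, out_file):
    """Associate hotspot strengths with SNP alleles by unpaired t-test."""
    with open(genotype_file) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        geno = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
    geno.columns = [str(c) for c in geno.columns]
    geno = maf_filter(geno, maf_floor)
    profiles = {}
    for p in profile_files:
        prof = read_profile(p)
        profiles[prof.hotspot_id] = prof.strengths
    table = gwas_scan(profiles, geno, threshold, welch=welch)
    table.to_csv(out_file, sep="\t", index=False)
    _write_manifest(Path(out_file).parent, "gwas",
                    {"threshold": threshold, "maf_floor": maf_floor, "welch": welch},
                    list(profile_files) + [genotype_file])
    click.echo(f"{int(table['significant'].sum())} significant of "
               f"{len(table)} tested pairs")


@cli.command()
@click.option("--grid", type=click.Choice(["default", "smoke"]), default="default",
              show_default=True)
@click.option("--reps", type=int, default=50, show_default=True)
@click.option("--seed", type=int, default=20150, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def evaluate(grid, reps, seed, out_dir):
    """Run the simulation study (scenario sweeps + dip experiment)."""
    from .evalharness import dip_experiment, roc_auc, run_experiment
    from .popsim import make_scenario_grid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if grid == "smoke":
        scenarios = [
            Scenario(seed=seed + r, hot_cold_ratio=ratio, tag=f"ratio={ratio}")
            for ratio in (1, 10)
            for r in range(reps)
        ]
        n2a = n_nv = max(2, reps)
    else:
        scenarios = make_scenario_grid(reps=reps, base_seed=seed)
        n2a = n_nv = 50
    results = run_experiment(scenarios, seed=seed)
    results.to_csv(out / "metrics.tsv", sep="\t", index=False)
    dip = dip_experiment(n2a, n_nv, base_seed=seed + 900_000)
    dip.to_csv(out / "dip_scores.tsv", sep="\t", index=False)
    roc = roc_auc(dip["neg_log10_p"], dip["variant"])
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "median_accuracy_by_scenario": results.groupby("scenario")["accuracy"]
                .median()
                .round(6)
                .to_dict(),
                "dip_auc": round(roc.auc, 6),
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    _write_manifest(out_dir, "evaluate",
                    {"grid": grid, "reps": reps, "seed": seed}, [])
    click.echo(f"dip ROC AUC = {roc.auc:.3f}; results in {out_dir}")


def cli_main(argv=None) -> int:
    """Entry point returning a process exit code (0 ok, 2 usage error)."""
    try:
        return cli.main(args=argv, standalone_mode=False) or 0
    except click.UsageError as exc:
        exc.show(file=sys.stderr)
        return 2
    except click.exceptions.Exit as exc:
        return exc.exit_code
    except click.Abort:
        return 130
    except Exception as exc:  # noqa: BLE001 - one-line diagnosis contract
        print(f"error: {exc}", file=sys.stderr)
        return 1


if __name__ == "__main__":
    raise SystemExit(cli_main())
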