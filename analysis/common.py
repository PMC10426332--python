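"""Shared configuration for the numbered analysis drivers.

Every driver runs the corresponding pipeline stage into ``results/`` with the
same run configuration (12 cities, 1987-2000 fitting period, horizon 2100,
seed 1), so the stages chain through their CSV artifacts exactly as the
command-line interface would.
"""

from pathlib import Path

from tempmort.cli import main as cli

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CONFIG = Path(__file__).resolve().parent / "config.yaml"


def run_stage(command: str) -> None:
    RESULTS.mkdir(exist_ok=True)
    cli(args=[command, "--outdir", str(RESULTS), "--config", str(CONFIG)],
        standalone_mode=False)
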