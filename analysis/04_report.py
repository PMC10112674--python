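#!/usr/bin/env python
"""Combine the three fitted models into one coefficient table.

Renders the owner/boarder/leaser fits side by side — coefficient and
robust SE per model, significance stars (* p<=0.10, ** p<=0.05,
*** p<=0.01), Ln(Sigma), the mean-WTP row, Wald chi-square and n — and
writes results/wtp_table.tsv and a Markdown twin.
"""
import argparse
import json
from pathlib import Path

from equiwtp.cli import _estimate_from_json, _fit_from_json
from equiwtp.report import format_results_table

parser = argparse.ArgumentParser()
parser.add_argument("--indir", type=Path, default=Path("results"))
args = parser.parse_args()

fits = []
for group in ("owner", "boarder", "leaser"):
    payload = json.loads((args.indir / f"fit_{group}.json").read_text())
    fits.append((group, _fit_from_json(payload), _estimate_from_json(payload)))

tsv = format_results_table(fits, fmt="tsv")
(args.indir / "wtp_table.tsv").write_text(tsv)
(args.indir / "wtp_table.md").write_text(format_results_table(fits, fmt="markdown"))
print(tsv)
print(f"wrote {args.indir / 'wtp_table.tsv'} and {args.indir / 'wtp_table.md'}")
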