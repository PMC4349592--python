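"""Regenerate the packaged synthetic lineage template.

The template (a Sulston-shaped tree with invented timings and positions,
~350 leaves) is deterministic; this script exists so the shipped data file
can be rebuilt and audited.  Run from the repository root:

    python scripts/make_template.py
"""

from pathlib import Path

from lineascope.simulate import synthesize_template, write_template_tsv

out = Path(__file__).resolve().parents[1] / "src/lineascope/data/lineage_template.tsv"
out.parent.mkdir(parents=True, exist_ok=True)
df = synthesize_template()
write_template_tsv(df, out)
print(f"wrote {out}: {len(df)} cells, "
      f"{(df.fate == 'terminal').sum()} terminal, {(df.fate == 'death').sum()} deaths")
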