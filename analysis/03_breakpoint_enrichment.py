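"""Test whether the MITE-like DAIBAM family is enriched at breakpoints.

Takes the strain1 breakpoint regions from 02, extends them to the called
end-points of any intersected repeat, and compares observed DAIBAM bp with
1000 length-matched random draws on the same contigs.
"""

import json
from pathlib import Path

from rearrkit.enrichment import permutation_test
from rearrkit.io_formats import read_bed, read_fasta, read_repeat_out

DATA = Path("results/data")
OUT = Path("results/enrichment")
SEED = 20260922


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    intervals = [(c, s, e) for c, s, e, *_ in
                 read_bed(Path("results/inversions/strain1.breakpoints.bed"))]
    hits = read_repeat_out(DATA / "repeats.out")
    lengths = {r.id: len(r) for r in read_fasta(DATA / "ancestor.fasta")}

    res = permutation_test(intervals, hits, "DAIBAM", lengths,
                           n_perm=1_000, seed=SEED)
    (OUT / "daibam_enrichment.json").write_text(json.dumps(
        {"observed_bp": res.observed_bp, "n_perm": res.n_perm,
         "n_ge": res.n_ge, "p_value": res.p_value,
         "subclass_pct": res.subclass_pct, "family_pct": res.family_pct},
        indent=1))
    print(f"observed DAIBAM bp in extended breakpoint regions: {res.observed_bp}")
    print(f"permutation p-value ({res.n_perm} draws): {res.p_value:.4g}")
    print("subclass content of extended regions (%):",
          {k: round(v, 1) for k, v in res.subclass_pct.items()})


if __name__ == "__main__":
    main()
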