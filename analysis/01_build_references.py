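#!/usr/bin/env python
"""Build the annotated D- and S-family 35S rDNA unit templates.

Writes the two unit FASTAs, their subregion annotation tables and a
restriction-site report.  The D unit is 8084 bp and the S unit 9215 bp;
both carry two BglII sites in the 25S gene (starts 3850 and 5185 on the
S unit), PstI sites in ITS2 (+IGS for S), one XhoI site each, and an
MluI site only in the D ITS1 (the CAPS diagnostic).
"""

from pathlib import Path

from rdnaprof import synthetic
from rdnaprof.digest import ENZYMES, find_sites

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    d_unit, s_unit = synthetic.make_default_units(seed=7)
    synthetic.write_fasta([d_unit, s_unit], OUT / "unit_templates.fasta")
    synthetic.write_subregions_tsv(d_unit, OUT / "d_unit_subregions.tsv")
    synthetic.write_subregions_tsv(s_unit, OUT / "s_unit_subregions.tsv")

    with open(OUT / "restriction_sites.tsv", "w") as handle:
        handle.write("unit\tenzyme\tmotif\tsites\n")
        for unit in (d_unit, s_unit):
            for name, enzyme in ENZYMES.items():
                sites = find_sites(unit, enzyme)
                handle.write(
                    f"{unit.name}\t{name}\t{enzyme.motif}\t"
                    f"{','.join(map(str, sites)) or '-'}\n"
                )
                print(f"{unit.name:7s} {name:6s} sites: {sites}")
    print(f"\nD unit {d_unit.length} bp, S unit {s_unit.length} bp")
    print(f"wrote templates and annotations to {OUT}")


if __name__ == "__main__":
    main()
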