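#!/usr/bin/env python
"""Seed-site localization and reporter-mutant construction for miR-30b.

Scans a synthetic two-site 3'UTR (mirroring the CCNE2 reporter configuration:
two miR-30b seed-match sites) for canonical site types, derives the mut1,
mut2 and mut1+2 constructs by 3-base transversions, verifies by rescanning
that site counts drop 2 -> 1 -> 0, and records the miR-30 seed family.
Writes results/seed_sites.tsv and results/constructs.fasta.
"""

from pathlib import Path

from trzmir.seeds import (
    MatureMiRNA,
    UTRSeq,
    find_seed_sites,
    mutate_seed_sites,
    seed_family,
    site_motifs,
)

ROOT = Path(__file__).resolve().parents[1] / "results"

MIR30 = {
    "miR-30a": "UGUAAACAUCCUCGACUGGAAG",
    "miR-30b": "UGUAAACAUCCUACACUCAGCU",
    "miR-30c": "UGUAAACAUCCUACACUCUCAGC",
    "miR-30d": "UGUAAACAUCCCCGACUGGAAG",
    "miR-30e": "UGUAAACAUCCUUGACUGGAAG",
}


def main() -> None:
    mir30b = MatureMiRNA("miR-30b", MIR30["miR-30b"])
    print(f"miR-30b seed (nt 2-8): {mir30b.seed}")
    fams = seed_family([MatureMiRNA(n, s) for n, s in MIR30.items()])
    for seed, members in fams.items():
        print(f"seed family {seed}: {', '.join(members)}")

    # synthetic stand-in for the CCNE2 3'UTR fragment: two 7mer-m8 sites
    m8 = site_motifs(mir30b)["7mer-m8"]
    utr = UTRSeq(
        "synthetic-CCNE2-UTR",
        "CCAGGCUAGC" + m8 + "AGGCUUAGGCAUCC" + m8 + "AGGCUAACGG",
    )
    sites = find_seed_sites(mir30b, utr)
    rows = ["construct\tn_sites\tsites"]

    def describe(label, seq):
        found = find_seed_sites(mir30b, UTRSeq(label, seq))
        desc = "; ".join(f"{s.site_type}@{s.as_1based()[0]}-{s.as_1based()[1]}" for s in found)
        rows.append(f"{label}\t{len(found)}\t{desc or '-'}")
        print(f"{label}: {len(found)} site(s) {desc}")
        return seq

    constructs = {"wt": describe("wt", utr.sequence)}
    constructs["mut1"] = describe(
        "mut1", mutate_seed_sites(utr, [sites[0]], mir30b, rng_seed=0).sequence)
    constructs["mut2"] = describe(
        "mut2", mutate_seed_sites(utr, [sites[1]], mir30b, rng_seed=0).sequence)
    constructs["mut1+2"] = describe(
        "mut1+2", mutate_seed_sites(utr, sites, mir30b, rng_seed=0).sequence)

    ROOT.mkdir(parents=True, exist_ok=True)
    (ROOT / "seed_sites.tsv").write_text("\n".join(rows) + "\n")
    with open(ROOT / "constructs.fasta", "w") as fh:
        for name, seq in constructs.items():
            fh.write(f">{name}\n{seq}\n")
    print(f"wrote {ROOT / 'seed_sites.tsv'} and {ROOT / 'constructs.fasta'}")


if __name__ == "__main__":
    main()
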