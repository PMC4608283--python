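"""Regenerate the bundled synthetic reference libraries.

Writes src/palm_ltr/data/synthetic_domain_refs.faa (labelled GAG/PR/INT/RT/RH
amino-acid references per superfamily and lineage; synthetic stand-ins for a
curated retroelement domain database — any FASTA with `>id|kind|superfamily|
lineage` headers is a drop-in replacement) and
src/palm_ltr/data/synthetic_trna_three_prime.fa (tRNA 3'-end stand-ins for
the primer-binding-site search).

Lineage references of one superfamily are generated as diverged copies of a
common ancestral sequence, so reverse-transcriptase references cluster by
superfamily and separate by lineage in a phylogeny, mirroring the structure
of real domain databases.

Deterministic; run from the repository root:  python scripts/make_ref_library.py
"""

from pathlib import Path

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"

COPIA_LINEAGES = ["Oryco", "Sire", "Retrofit", "Tork"]
GYPSY_LINEAGES = ["Athila", "Tat", "CRM", "Del", "Galadriel", "G-Rhodo", "Reina"]

DOMAIN_LENGTHS = {"GAG": 150, "PR": 100, "INT": 250, "RT": 220, "RH": 150}


def random_protein(n, rng):
    return "".join(rng.choice(list(AA), size=n))


def diverge_protein(seq, rate, rng):
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([a for a in AA if a != c]))
        else:
            out.append(c)
    return "".join(out)


def main() -> None:
    rng = np.random.default_rng(20151015)
    records = []
    for superfamily, lineages in [("Copia", COPIA_LINEAGES), ("Gypsy", GYPSY_LINEAGES)]:
        # one ancestral sequence per domain kind per superfamily
        ancestors = {kind: random_protein(n, rng) for kind, n in DOMAIN_LENGTHS.items()}
        for kind in ["GAG", "PR", "INT", "RH"]:
            records.append((f"{superfamily}_{kind}", kind, superfamily, "-",
                            ancestors[kind]))
        # RT diverges per lineage so trees resolve lineages within superfamilies
        for lineage in lineages:
            rt = diverge_protein(ancestors["RT"], 0.25, rng)
            records.append((f"{superfamily}_{lineage}_RT", "RT", superfamily,
                            lineage, rt))

    data_dir = Path(__file__).resolve().parent.parent / "src" / "palm_ltr" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    with open(data_dir / "synthetic_domain_refs.faa", "w") as fh:
        for rid, kind, sf, lineage, seq in records:
            fh.write(f">{rid}|{kind}|{sf}|{lineage}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    # tRNA 3' ends: 15 nt ending in the universal CCA
    trnas = {}
    for name in ["tRNA-iMet", "tRNA-Lys", "tRNA-Pro", "tRNA-Trp", "tRNA-Gly"]:
        trnas[name] = "".join(rng.choice(list("ACGT"), size=12)) + "CCA"
    with open(data_dir / "synthetic_trna_three_prime.fa", "w") as fh:
        for name, seq in trnas.items():
            fh.write(f">{name}\n{seq}\n")
    print(f"wrote {len(records)} domain refs and {len(trnas)} tRNA ends to {data_dir}")


if __name__ == "__main__":
    main()
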