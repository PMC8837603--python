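# npstpipe

A self-contained pipeline for mining NRPS adenylation-domain (A-domain)
amplicons from pooled, barcoded metagenomic libraries and predicting the
structure of the encoded non-ribosomal peptide:

1. **synthetic** — seeded generators for characterized A-domain reference
   panels (protein + in-frame nucleotide sequence + 10-residue pocket code),
   pooled clone libraries with planted amplicon templates, substitution-error
   reads, and the transcribed assembly-line architecture of the bundled
   worked example (an N-acylated decapeptide).
2. **amplicon** — in-silico PCR with the shipped degenerate primers
   (`AD-FW: GCSTACSYSATSTACACSTCSGG`, `AD-RV: SASGTCVCCSGTSCGGTA`),
   exact-barcode demultiplexing with primer trimming, and greedy centroid
   clustering of reads into natural product sequence tags (NPSTs) at 95%
   global-alignment identity.
3. **screen** — the two-step PABA screen: Smith–Waterman/BLOSUM62 alignment
   of the translated centroid against known PABA-specific A-domains with a
   Karlin–Altschul E-value cutoff (default `1e-25`), then an exact match of
   the degenerate signature `ARAARA (N11) TTYGCNRT (N7) AARGAR` on either
   strand.
4. **phylogeny** — deterministic progressive alignment, neighbor joining on
   p-distances, and calling of maximal reference-free clades (≥ 2 NPSTs, no
   characterized reference) as candidate novel BGC families.
5. **adomain** — extraction of the 10 substrate-binding-pocket residues
   (coordinates 235, 236, 239, 278, 299, 301, 322, 330, 331, 517 in the
   shipped anchor's numbering) and nearest-code substrate prediction with
   tie reporting and a position-299 variability annotation; A3/A7 core-motif
   activity calling.
6. **structure** — a rule engine that orders proteins into an assembly line
   (Cs starter first, TE terminus last), resolves inactive modules through
   trans-acting standalone A-domains, forms thiazoline/thiazole rings from
   Cy + Cys modules (promoted by an FMN oxidase), validates AHIBA tailoring
   support, and emits the monomer-level product with class counts and an
   N-terminal β-hydroxy lipid.

## CLI

All functionality is exposed through the `npst` command:

```sh
npst simulate --n-paba 3 --n-other 5 --pools 2 --clones 50 --seed 1 --out sim/
npst scan contigs.fasta --min-len 200 --max-len 3000 --out amplicons.fasta
npst demux sim/reads.fasta --barcodes sim/barcodes.tsv --out demux/
npst cluster demux/assigned.fasta --identity 0.95 --out clusters/
npst screen clusters/npst.fasta --refs paba_refs.fasta --out screen.tsv
npst tree seqs.fasta --classes classes.tsv --out tree.nwk --calls calls.tsv
npst code proteins.fasta --out codes.tsv
npst predict --lap-fixture --report report.json
npst lap-architecture --out arch.json     # annotation-table JSON schema
```

`npst simulate --config sim.yaml` accepts a YAML file whose keys mirror the
flags. `npst predict` consumes the annotation-table JSON written by
`lap-architecture` (proteins → modules → domains/substrate/activity, plus
tailoring genes and standalone A-domains).

Running `npst predict --lap-fixture` prints the worked example:

```
C14-bOH—Ala—Ser—Ala—PABA—Cys(thiazole)—Cys(thiazole)—Asn—PABA—AHIBA—PABA
```

## Layout

```
src/npstpipe/     package modules (synthetic, amplicon, screen,
                  phylogeny, adomain, structure, cli)
tests/            pytest suite; tests/test_acceptance.py holds the
                  acceptance criteria
scripts/          acceptance.py
```
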