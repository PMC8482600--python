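# spacerscope

CRISPR arrays record a microbe's encounters with mobile genetic elements as
*spacers*. Mapping spacers back to their targets (*protospacers*) in sequence
databases exposes the mechanics of CRISPR-Cas defense: the protospacer
adjacent motif (PAM) each system requires, the transcription orientation of
the array, whether crRNAs target the coding or template strand of genes (and
hence whether they can also base-pair mRNA), and whether co-occurring
CRISPR-Cas systems share spacers, repeats or acquisition machinery.

`spacerscope` is a tested, reusable implementation of that analysis for
microbial genomicists: from a spacer/repeat table and candidate target
sequences to filtered protospacer hits, repeat clusters, GC-corrected PAM and
orientation calls, repeat–PAM concordance, strand-bias statistics and
multi-effector compatibility categories. A fully labeled synthetic-data
generator stands in for the database-scale inputs, so every stage has a
recoverable ground truth.

## The method in brief

* **Matching & filtering.** Spacers are matched to subjects with a
  seed-and-extend nucleotide search (exact 10-mer seeds, both strands, gapped
  extension), or pre-computed BLAST outfmt-6 hits (+`qlen`,`nident`) are
  ingested. Hits inside CRISPR arrays are removed when the spacer's repeat
  aligns to a 23-nt hit flank with more than 13 net identities. The matched
  fraction `nident / qlen` then drives a two-step filter: keep > 90%; keep
  > 80% only on subjects that already received a step-1 hit from another
  spacer of the same genus (step 2 can never introduce a new subject).
* **Repeat clusters.** Repeats cluster greedily at ≥ 90% global identity and
  equal length; subtypes come from reference repeats at a 74% identity floor.
* **PAM and orientation.** Per cluster, each spacer contributes one
  consensus flank pair (plurality base per position over its hits; duplicate
  pairs collapse to one "unique protospacer"). Per-position conservation is
  the relative entropy in bits against a background from the cluster's mean
  spacer GC, `ic_i = Σ_b f_{b,i} log2(f_{b,i}/p_b)` with
  `p_A = p_T = (1−GC)/2`, `p_C = p_G = GC/2`. A flank side *qualifies* for
  orientation when ≥ 2 positions exceed 0.3 bits and 5× the median over all
  46 flank positions; because the PAM is 5′ of the protospacer in type I/IV/V
  and 3′ in type II, the qualifying side fixes the array orientation. PAM
  positions are flagged at 0.5 bits and 10× median (≥ 10 unique protospacers,
  ≥ 2 positions), rendered as IUPAC codes by a 0.8 cumulative-frequency rule.
* **Strand bias.** For each spacer's primary target (longest
  nucleotide-database subject), hits fully inside one ORF are classified:
  a crRNA matching the template strand targets the coding strand and can
  also base-pair the mRNA. Group bias is tested with the exact two-sided
  binomial test at p₀ = 0.5.
* **Co-occurrence.** Arrays link to cas gene clusters within 25 kb. Genomes
  are classified into three multi-effector compatible organizations:
  (1) two DNA-targeting systems sharing a PAM with their own repeats,
  (2) a DNA- and an RNA-targeting system sharing a PAM with distinct
  repeats, (3) one repeat cluster serving cas clusters of different subtypes.

## Worked example

Generate a synthetic universe (20 repeat clusters × 30 spacers, planted
3-nt PAMs at 90% adherence, planted orientations, ORF-embedded targets,
decoys and array-embedded self-hits), then run the full pipeline:

```bash
spacerscope simulate --seed 5 --out universe
# wrote universe (618 spacers, 1222 subjects) to universe
spacerscope report --spacers universe/spacers.csv \
    --subjects universe/subjects.fasta --gff universe/orfs.gff3 \
    --out-dir report
```

`report/pam_catalog.csv` lists the called PAM per repeat cluster — here the
planted motifs come back verbatim, e.g.:

```
repeat,PAM,subtype
GACACATGGGCGTAACGTAGCATTGAAAC,TTC,I-C
GAGTGCCCCGTAGTATCAGTAATTGAAAC,AAG,I-E
ATGCGGATATACGGAGACGATATTGAAAC,TTA,I-B
```

`report/orientations.csv` gives the per-cluster orientation with the
qualifying-position counts per side (`rc0000,reverse,pam_based,1.0,6.0`
means six qualifying downstream positions flipped this type II cluster),
and `report/strand_bias.csv` the per-subtype coding/template counts with
exact binomial p-values; with the generator's default 50% coding fraction
no group is significant, e.g. `I-B,61,58,0.5126,0.85,0`.

As a calibration of the statistic itself: 611 template-strand calls out of
977 ORF-contained matches — the classic *Escherichia* I-E configuration —
is 63% template-strand targeting with an exact two-sided binomial
p ≈ 4·10⁻¹⁵, far below e⁻¹⁴.

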