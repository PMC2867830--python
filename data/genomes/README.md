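# Deposited genomes for the PCR verification check

One acceptance check predicts PCR product sizes for the primer pairs flanking
the polyketide synthesis operon on the two deposited genomes. It needs the
sequences locally (they are too large to ship with the package):

- `AL009126.fa` — *Bacillus subtilis* subsp. *subtilis* str. 168 chromosome
- `AP011541.fa` — *Bacillus subtilis* subsp. *natto* BEST195 chromosome

Download once with any of:

    # NCBI E-utilities
    curl -o AL009126.fa 'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=AL009126.3&rettype=fasta&retmode=text'
    curl -o AP011541.fa 'https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=AP011541&rettype=fasta&retmode=text'

    # or EBI ENA
    curl -o AL009126.fa 'https://www.ebi.ac.uk/ena/browser/api/fasta/AL009126.3'
    curl -o AP011541.fa 'https://www.ebi.ac.uk/ena/browser/api/fasta/AP011541.1'

Without these files the corresponding test reports failure (it is the one
check that cannot run offline); everything else in the suite is self-contained.
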