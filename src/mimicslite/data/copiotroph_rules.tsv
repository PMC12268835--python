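# Demonstration copiotroph/oligotroph classification rules (rank, taxon, group).
# Multi-rank on purpose: finer ranks override coarser ones, e.g. the genus
# Bradyrhizobium (oligotroph) overrides its class Alphaproteobacteria
# (copiotroph).  This small set illustrates the grouping machinery; it is NOT
# a literature-complete rule table, which users should supply themselves.
phylum	Bacteroidetes	copiotroph
phylum	Firmicutes	copiotroph
phylum	Acidobacteria	oligotroph
phylum	Planctomycetes	oligotroph
phylum	Verrucomicrobia	oligotroph
phylum	Chloroflexi	oligotroph
class	Alphaproteobacteria	copiotroph
class	Gammaproteobacteria	copiotroph
order	Enterobacterales	copiotroph
family	Chitinophagaceae	copiotroph
genus	Bradyrhizobium	oligotroph
genus	Streptomyces	copiotroph
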