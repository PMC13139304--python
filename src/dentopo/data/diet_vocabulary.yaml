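# Dietary category vocabulary for specimen tables.
# Categories are defined by the dominant food type; alternative published
# classification schemes can be swapped in by pointing the loader at a
# different vocabulary file.
version: 1
diets:
  - faunivore              # regular consumption of vertebrate prey
  - folivore               # leaves form the majority of the diet
  - frugivore              # fruit-dominated
  - frugivore-insectivore  # fruit and invertebrates both major components
  - insectivore            # invertebrate-dominated, little fruit
  - hard-object feeder     # mechanically hard items (nuts, hard seeds)
  - omnivore               # animals, fruit and other plant parts all major
loci:
  - m2
  - m3
clades:
  - marsupial
  - primate
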