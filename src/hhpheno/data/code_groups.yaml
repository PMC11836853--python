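# Named code groups used by the phenotyping algorithms.
#
# Values are code prefixes in any dot dialect; they are normalised
# (upper case, dots stripped) at load time. A prefix captures every
# code that extends it, so "D56" covers D560, D561, ...
#
# G1: non-haemochromatosis conditions treated with venesection.
# G2: haematological conditions associated with transfusion-related
#     iron overload.
G1:
  - D45      # polycythaemia vera
  - D75.1    # secondary polycythaemia
  - E80.1    # porphyria cutanea tarda
G2:
  - D46      # myelodysplastic syndromes
  - D47.4    # osteomyelofibrosis
  - D55      # anaemia due to enzyme disorders
  - D56      # thalassaemia
  - D57      # sickle cell disorders
  - D58      # other hereditary haemolytic anaemias
  - D59      # acquired haemolytic anaemia
  - D60      # acquired pure red cell aplasia
  - D61      # other aplastic anaemias
  - C91      # lymphoid leukaemia
  - C92      # myeloid leukaemia
  - C93      # monocytic leukaemia
  - C94      # other leukaemias of specified cell type
  - C95      # leukaemia of unspecified cell type
E831:
  - E83.1    # disorders of iron metabolism (cohort-defining diagnosis)
X362:
  - X36.2    # venesection (OPCS-4 procedure)
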