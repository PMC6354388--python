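11
Dakar
1
Thies
Diourbel
3
Fatick Louga Thies
Fatick
3
Diourbel Kaolack Thies
Kaolack
3
Fatick Kolda Tambacounda
Kolda
3
Kaolack Tambacounda Ziguinchor
Louga
5
Diourbel Matam SaintLouis Tambacounda Thies
Matam
3
Louga SaintLouis Tambacounda
SaintLouis
2
Louga Matam
Tambacounda
4
Kaolack Kolda Louga Matam
Thies
4
Dakar Diourbel Fatick Louga
Ziguinchor
1
Kolda
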