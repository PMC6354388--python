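14
Dakar
1
Thies
Diourbel
3
Fatick Louga Thies
Fatick
4
Diourbel Kaolack Kaffrine Thies
Kaolack
6
Fatick Kaffrine Kolda Sedhiou Tambacounda Kedougou
Kaffrine
6
Fatick Kaolack Kolda Sedhiou Tambacounda Kedougou
Kolda
6
Kaolack Kaffrine Sedhiou Tambacounda Kedougou Ziguinchor
Sedhiou
6
Kaolack Kaffrine Kolda Tambacounda Kedougou Ziguinchor
Louga
6
Diourbel Matam SaintLouis Tambacounda Kedougou Thies
Matam
4
Louga SaintLouis Tambacounda Kedougou
SaintLouis
2
Louga Matam
Tambacounda
7
Kaolack Kaffrine Kolda Sedhiou Louga Matam Kedougou
Kedougou
7
Kaolack Kaffrine Kolda Sedhiou Louga Matam Tambacounda
Thies
4
Dakar Diourbel Fatick Louga
Ziguinchor
2
Kolda Sedhiou
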