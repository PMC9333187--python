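province,average_insecure_pct
East Azerbaijan,29.0
West Azerbaijan,20.6
Ardebil,15.1
Isfahan,42.8
Ilam,10.5
Bushehr,39.9
Tehran,47.6
Chaharmahal and Bakhtiari,37.8
South Khorasan,9.3
Razavi Khorasan,20.7
North Khorasan,26.7
Khuzestan,19.9
Zanjan,21.4
Semnan,48.7
Sistan and Baluchistan,20.2
Fars,21.3
Qazvin,24.0
Qom,55.9
Kurdistan,22.0
Kerman,26.3
Kermanshah,9.5
Kohgiluyeh and Boyer-Ahmad,49.0
Golestan,46.1
Gilan,46.3
Lorestan,29.8
Mazandaran,37.7
Markazi,32.6
Hormozgan,48.2
Hamedan,20.1
Yazd,54.0
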