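case_id,physician,department,patient_sex,birth_date,age_years,consult_date,consult_season,symptoms,syndrome,elements,element_categories,disease_name
t1,dr01,internal,female,1962-03-11,59,2021-04-20,spring,"Epigastric-pain, cracked-tongue, white-coating, stringy pulse","Deficiency of vital energy, congestion of heat and toxins.","zheng, qi, kui, xu, re, du, yong, sheng","b, b, d, d, c, c, d, d",Stomach ache
t2,dr02,internal,male,1979-08-02,42,2021-11-05,autumn,"Nausea, vomiting, abdominal pain, vexation, fatigue, fat tongue, yellow moss, greasy moss, fine veins",Internal obstruction by wetness,"Shi, xie, nei, zu","c, c, d",Vomiting
t3,dr02,internal,female,1990-01-15,31,2021-07-19,summer,"Generalized vomiting, excessive salivation, pale mouth, pale red tongue, white moss, sluggish pulse",Rebellious cold in the stomach,"Wei, han, shang, ni","a, c, a, d",Vomiting
t4,dr03,hepatology,male,1955-06-30,66,2022-01-12,winter,"Weakness, Yellow urine, Stringy pulse","Stagnant heat in the liver meridian, blood stasis","gan jing, yu, re, yu","a, d, c, c",Liver accumulation
t5,dr01,cardiology,female,1948-12-09,73,2022-03-02,spring,"Tightness in chest, palpitation, shortness of breath, poor appetite, poor sleep, dry stools, dark red tongue, scanty coating",Double deficiency of the heart and spleen,"xue, xin, xu, qi, pi","b, a, d, b, a",Tachycardia
t6,dr04,ophthalmology,male,1971-05-23,50,2021-09-28,autumn,"Eye pain, itchy eyes, red tongue, thin moss, white moss, fine pulse, stringy pulse",Deficiency of liver and kidney,"gan, xu, shen","a, d, a",Cataract
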