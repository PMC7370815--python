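image_id,order_index,date_label,condition,path
img01,1,t01,low,img01.png
img02,2,t02,low,img02.png
img03,3,t03,low,img03.png
img04,4,t04,low,img04.png
img05,5,t05,low,img05.png
img06,6,t06,low,img06.png
img07,7,t07,low,img07.png
img08,8,t08,low,img08.png
img09,9,t09,high,img09.png
img10,10,t10,high,img10.png
img11,11,t11,high,img11.png
img12,12,t12,high,img12.png
img13,13,t13,low,img13.png
img14,14,t14,low,img14.png
img15,15,t15,low,img15.png
img16,16,t16,low,img16.png
img17,17,t17,low,img17.png
img18,18,t18,low,img18.png
img19,19,t19,low,img19.png
img20,20,t20,low,img20.png
img21,21,t21,high,img21.png
img22,22,t22,high,img22.png
img23,23,t23,high,img23.png
img24,24,t24,low,img24.png
img25,25,t25,low,img25.png
img26,26,t26,low,img26.png
img27,27,t27,high,img27.png
img28,28,t28,high,img28.png
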